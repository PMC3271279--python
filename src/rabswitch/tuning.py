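"""Sobol'-sampling hyper-parameter tuning for the meta-heuristics.

Four hyper-parameters per method are sampled from a Sobol' low-discrepancy
sequence over the unit hypercube, mapped affinely onto their ranges
(integers rounded to nearest; conditional upper bounds such as K <= S-1 for
PSO and s_minus <= rho for DASA applied using the already-mapped
controlling coordinate), and each setting is scored by the median final
objective over several independently seeded runs.  The setting with the
minimal median wins; ties break by mean, then by sampling order.

The study-scale harness (2000 settings x 8 runs x 5e5 evaluations on
noise-free complete-observation data) is expressible with the same calls;
tests exercise the machinery at toy scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .optimizers import DASAConfig, DEConfig, PSOConfig

__all__ = [
    "TuningSpace",
    "TuningResult",
    "DE_SPACE",
    "PSO_SPACE",
    "DASA_SPACE",
    "sobol_points",
    "map_to_space",
    "make_config",
    "tune",
]


@dataclass(frozen=True)
class TuningSpace:
    """Four named hyper-parameters with ranges, integer flags and conditions.

    ``conditional_upper`` maps a parameter name to the name of the
    already-mapped parameter that caps it (the cap is controller - 1 for
    integers, controller itself otherwise).
    """

    names: tuple[str, str, str, str]
    lower: tuple[float, float, float, float]
    upper: tuple[float, float, float, float]
    integer: tuple[bool, bool, bool, bool]
    conditional_upper: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.names) != 4:
            raise ValueError("a tuning space has exactly four dimensions")
        for dep, ctrl in self.conditional_upper.items():
            if dep not in self.names or ctrl not in self.names:
                raise ValueError("conditional bounds must reference space names")
            if self.names.index(ctrl) >= self.names.index(dep):
                raise ValueError("controller must be listed before dependent")


DASA_SPACE = TuningSpace(
    names=("ants", "evaporation", "scale_increase", "scale_decrease"),
    lower=(4, 0.0, 0.0, 0.0), upper=(200, 1.0, 1.0, 1.0),
    integer=(True, False, False, False),
    conditional_upper={"scale_decrease": "evaporation"},
)

PSO_SPACE = TuningSpace(
    names=("swarm", "neighborhood", "inertia", "acceleration"),
    lower=(4, 1, 0.0, 1.0), upper=(200, 199, 1.0, 4.0),
    integer=(True, True, False, False),
    conditional_upper={"neighborhood": "swarm"},
)

DE_SPACE = TuningSpace(
    names=("population", "strategy", "weight", "crossover"),
    lower=(6, 1, 0.0, 0.0), upper=(200, 10, 2.0, 1.0),
    integer=(True, True, False, False),
)

_SPACES = {"dasa": DASA_SPACE, "pso": PSO_SPACE, "de": DE_SPACE}


def sobol_points(dim: int, n: int, skip_origin: bool = True) -> np.ndarray:
    """First ``n`` points of the Gray-code Sobol' sequence in [0, 1)^dim.

    The all-zeros leading point is skipped by default (configurable), so the
    first emitted point is deterministic and nontrivial.
    """
    if dim < 1 or n < 1:
        raise ValueError("dim and n must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # unbalanced n is fine here
        sampler = qmc.Sobol(d=dim, scramble=False)
        if skip_origin:
            sampler.fast_forward(1)
        return sampler.random(n)


def map_to_space(unit_point, space: TuningSpace) -> dict:
    """Affinely map a unit-hypercube point onto a tuning space.

    Integers round to nearest; conditional upper bounds use the
    already-mapped controlling coordinate.
    """
    u = np.asarray(unit_point, dtype=float)
    if u.shape != (4,) or np.any(u < 0) or np.any(u >= 1):
        raise ValueError("unit_point must lie in [0, 1)^4")
    setting: dict = {}
    for i, name in enumerate(space.names):
        hi = space.upper[i]
        if name in space.conditional_upper:
            ctrl = setting[space.conditional_upper[name]]
            hi = min(hi, ctrl - 1 if space.integer[i] else ctrl)
        lo = space.lower[i]
        val = lo + u[i] * (hi - lo)
        if space.integer[i]:
            val = int(round(val))
            val = min(max(val, int(lo)), int(hi) if hi >= lo else int(lo))
        setting[name] = val
    return setting


def make_config(method: str, setting: dict):
    """Build the optimizer config object for a mapped setting."""
    key = method.lower()
    if key == "de":
        return DEConfig(**setting)
    if key == "pso":
        return PSOConfig(**setting)
    if key == "dasa":
        return DASAConfig(**setting)
    raise ValueError(f"no tunable configuration for method {method!r}")


@dataclass
class TuningResult:
    settings: list
    medians: np.ndarray
    means: np.ndarray
    selected_index: int

    @property
    def selected(self) -> dict:
        return self.settings[self.selected_index]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.settings)
        df["median_best"] = self.medians
        df["mean_best"] = self.means
        return df


def tune(method: str, objective, bounds, n_settings: int, runs_per_setting: int,
         budget: int, base_seed: int = 0, space: TuningSpace | None = None,
         residuals_fn=None) -> TuningResult:
    """Sample settings, run each several times, select by median best objective."""
    from .optimizers import run_method

    space = space or _SPACES[method.lower()]
    points = sobol_points(4, n_settings)
    settings = []
    medians = np.empty(n_settings)
    means = np.empty(n_settings)
    for j in range(n_settings):
        setting = map_to_space(points[j], space)
        settings.append(setting)
        finals = []
        for r in range(runs_per_setting):
            seed = base_seed + 1009 * j + r
            res = run_method(method, objective, bounds, budget, seed,
                             config=make_config(method, setting),
                             residuals_fn=residuals_fn)
            finals.append(res.best_objective)
        medians[j] = np.median(finals)
        means[j] = np.mean(finals)
    # minimal median; ties by mean, then first sampled
    order = np.lexsort((np.arange(n_settings), means, medians))
    return TuningResult(settings, medians, means, int(order[0]))
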