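"""Multi-run evaluation: ensembles, summaries, convergence curves, Holm test.

A *problem* is one scenario/noise combination; a *run ensemble* is a set of
independently seeded optimizer runs on one problem.  Per-run quality is
reported as RMSE (output reconstruction against the dataset) and, when a
reference trajectory is available, RMSEm (reconstruction of the full hidden
dynamics).  Methods are compared across problems with a Friedman-style
ranking (per-problem ranks 0 = best, averaged across problems) followed by
the step-down Holm post-hoc test against the best-ranked method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .model import ParameterVector, TimeGrid, simulate
from .objectives import ObjectiveContext, rmse, rmsem
from .optimizers import ConvergenceTrace, OptimizerResult, SearchBounds, run_method

__all__ = [
    "RunEnsemble",
    "BoxplotSummary",
    "HolmResult",
    "run_ensemble",
    "boxplot_summary",
    "average_convergence",
    "log_checkpoints",
    "holm_test",
    "plot_boxplots",
    "plot_convergence",
    "BENCHMARK_PROBLEMS",
    "BENCHMARK_MEDIAN_RMSE",
    "BENCHMARK_MEDIAN_RMSEM",
]

#: The twelve benchmark problems: four observation scenarios at three
#: relative noise levels.
BENCHMARK_PROBLEMS = tuple(
    f"{sc}-{int(s * 100)}" for s in (0.0, 0.05, 0.2) for sc in ("co", "ao", "to", "npo")
)

_METHOD_ORDER = ("dasa", "pso", "de", "a717")

#: Reference median errors over 25 runs of half a million evaluations each,
#: for the four estimation methods on the twelve scenario/noise problems
#: (full-scale ensembles; reproducing them is a multi-CPU-week computation).
#: Rows follow BENCHMARK_PROBLEMS, columns _METHOD_ORDER.
BENCHMARK_MEDIAN_RMSE = pd.DataFrame(
    [
        [0.0651, 0.0527, 0.0189, 0.7005],
        [0.0625, 0.0539, 0.0250, 0.6099],
        [0.0951, 0.1507, 0.0197, 0.6612],
        [0.2993, 0.5040, 0.2282, 0.6881],
        [0.1164, 0.1121, 0.0999, 0.7287],
        [0.0902, 0.0861, 0.0690, 0.6232],
        [0.1363, 0.1341, 0.1006, 0.6546],
        [0.3162, 0.5166, 0.2463, 0.6897],
        [0.3958, 0.3941, 0.3907, 0.8113],
        [0.2770, 0.2760, 0.2707, 0.6782],
        [0.4023, 0.3983, 0.3917, 0.7810],
        [0.4929, 0.6407, 0.4585, 0.8023],
    ],
    index=list(BENCHMARK_PROBLEMS), columns=list(_METHOD_ORDER),
)

BENCHMARK_MEDIAN_RMSEM = pd.DataFrame(
    [
        [0.0651, 0.0527, 0.0189, 0.7005],
        [1.6272, 0.7866, 1.7876, 1.0684],
        [0.5857, 0.4606, 0.2511, 0.7960],
        [2.6840, 2.0717, 3.9246, 3.0273],
        [0.1164, 0.1121, 0.0999, 0.7287],
        [1.0437, 0.9043, 1.4639, 1.3442],
        [0.6162, 0.2750, 0.2831, 0.9265],
        [2.8668, 3.8831, 6.6315, 2.1172],
        [0.3958, 0.3941, 0.3907, 0.8113],
        [1.7547, 1.0050, 2.8513, 1.3052],
        [0.6967, 0.4606, 0.4289, 0.9952],
        [2.1250, 2.5423, 2.8333, 2.1999],
    ],
    index=list(BENCHMARK_PROBLEMS), columns=list(_METHOD_ORDER),
)


@dataclass
class RunEnsemble:
    """Independently seeded runs of one method on one problem."""

    method: str
    scenario: str
    noise_level: float
    budget: int
    results: list
    rmse_values: np.ndarray
    rmsem_values: np.ndarray | None = None

    def summary(self) -> pd.Series:
        """Best / Median / Worst / Average / Std of the per-run RMSE."""
        v = self.rmse_values
        return pd.Series(
            [v.min(), float(np.median(v)), v.max(), v.mean(), v.std(ddof=1) if v.size > 1 else 0.0],
            index=["Best", "Median", "Worst", "Average", "Std"], name=self.method,
        )


def run_ensemble(method: str, ctx: ObjectiveContext, n_runs: int = 25,
                 budget: int = 500_000, base_seed: int = 0, config=None,
                 reference_trajectory=None, grid: TimeGrid | None = None) -> RunEnsemble:
    """Run ``method`` ``n_runs`` times on the dataset in ``ctx``.

    Per-run RMSE derives from the best objective; RMSEm is computed when a
    reference trajectory is supplied (infeasible best points get NaN).
    """
    from .objectives import residuals as _residuals

    bounds = SearchBounds.default()
    results = []
    rmses = np.empty(n_runs)
    rmsems = np.empty(n_runs) if reference_trajectory is not None else None
    for r in range(n_runs):
        res = run_method(method, ctx, bounds, budget, base_seed + r, config=config,
                         residuals_fn=lambda x: _residuals(x, ctx))
        results.append(res)
        rmses[r] = rmse(res.best_objective, ctx.n_samples)
        if rmsems is not None:
            try:
                traj = simulate(ParameterVector(res.best_params), grid,
                                rel_tol=ctx.rel_tol, abs_tol=ctx.abs_tol)
                rmsems[r] = rmsem(traj, reference_trajectory)
            except Exception:
                rmsems[r] = np.nan
    return RunEnsemble(method, ctx.dataset.scenario.name, ctx.dataset.noise_level,
                       budget, results, rmses, rmsems)


@dataclass
class BoxplotSummary:
    """The numbers behind a box-and-whisker diagram."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    notch_halfwidth: float
    mean: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles, 1.5*IQR whiskers, outliers and the median notch half-width."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotSummary(
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
        notch_halfwidth=float(1.57 * iqr / np.sqrt(v.size)),
        mean=float(v.mean()),
    )


def average_convergence(traces: list, checkpoints) -> tuple[np.ndarray, np.ndarray]:
    """Mean best-so-far value over traces at shared evaluation checkpoints.

    Checkpoints are typically log-spaced; every checkpoint must be covered
    by at least one evaluation in every trace.
    """
    if not traces:
        raise ValueError("need at least one trace")
    cps = np.asarray(checkpoints, dtype=np.int64)
    curve = np.empty((len(traces), cps.size))
    for i, tr in enumerate(traces):
        for j, k in enumerate(cps):
            b = tr.best_at(int(k))
            if not np.isfinite(b):
                raise ValueError(f"checkpoint {k} precedes the first evaluation "
                                 "of a trace")
            curve[i, j] = b
    return cps, curve.mean(axis=0)


def log_checkpoints(budget: int, n: int = 50) -> np.ndarray:
    """n log-spaced evaluation checkpoints in [1, budget]."""
    return np.unique(np.round(np.geomspace(1, budget, n)).astype(np.int64))


@dataclass
class HolmResult:
    """Average ranks and the step-down Holm comparison against the best method."""

    methods: list
    average_ranks: np.ndarray
    reference_method: str
    table: pd.DataFrame  # per non-reference method: i, alpha_over_i, z, p, rejected

    def z_of(self, method: str) -> float:
        return float(self.table.loc[method, "z"])


def holm_test(median_table, alpha: float = 0.05) -> HolmResult:
    """Friedman-style average ranks plus the Holm post-hoc test.

    ``median_table`` is a (methods x problems) DataFrame or array of
    quality values where lower is better.  Methods are ranked 0..Nm-1
    within each problem (ties get mid-ranks), ranks are averaged across the
    Ntp problems, and each non-reference method i (ordered worst first,
    i = Nm-1..1) gets z_i = |r0 - r_i| / sqrt(Nm (Nm+1) / (6 Ntp)) with a
    two-sided normal p-value compared step-down against alpha / i.
    """
    if isinstance(median_table, pd.DataFrame):
        methods = list(median_table.index)
        values = median_table.to_numpy(dtype=float)
    else:
        values = np.asarray(median_table, dtype=float)
        methods = [f"method{i}" for i in range(values.shape[0])]
    nm, ntp = values.shape
    if nm < 2 or ntp < 1:
        raise ValueError("need >= 2 methods and >= 1 problem")
    ranks = np.empty_like(values)
    for j in range(ntp):
        ranks[:, j] = rankdata(values[:, j], method="average") - 1.0
    avg = ranks.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    ref = order[0]
    se = np.sqrt(nm * (nm + 1) / (6.0 * ntp))
    rows = []
    rejected_so_far = True
    # worst-ranked first: i = Nm-1 down to 1
    for pos, idx in enumerate(order[:0:-1]):
        i = nm - 1 - pos
        z = abs(avg[ref] - avg[idx]) / se
        p = 2.0 * norm.sf(z)
        reject = rejected_so_far and (p < alpha / i)
        rejected_so_far = reject
        rows.append((methods[idx], i, alpha / i, z, p, reject))
    table = pd.DataFrame(rows, columns=["method", "i", "alpha_over_i", "z", "p",
                                        "rejected"]).set_index("method")
    return HolmResult(methods, avg, methods[ref], table)


def plot_boxplots(samples: dict, path, ylabel: str = "RMSE",
                  log_scale: bool = True) -> None:
    """Notched box-and-whisker comparison of per-method value samples.

    ``samples`` maps method name to a 1-D array of per-run values; the
    figure is written to ``path``.  The same numbers are available from
    :func:`boxplot_summary`, so the graphic is a convenience, not the
    record.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.6 * len(samples) + 1.5, 3.5))
    names = list(samples)
    ax.boxplot([np.asarray(samples[m], dtype=float) for m in names],
               notch=True, whis=1.5, showmeans=True, tick_labels=names)
    if log_scale:
        ax.set_yscale("log")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_convergence(curves: dict, path, ylabel: str = "best objective") -> None:
    """Log-log averaged convergence curves, one per method.

    ``curves`` maps method name to (checkpoints, values) as returned by
    :func:`average_convergence`.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, (cps, vals) in curves.items():
        ax.loglog(cps, vals, label=name)
    ax.set_xlabel("objective evaluations")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
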