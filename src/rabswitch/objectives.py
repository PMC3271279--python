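"""Error metrics and the penalized estimation objective.

The objective minimized by every optimizer is the sum of squared errors
(SSE) between a dataset's observed outputs and the model prediction under
the dataset's scenario.  Candidate parameter vectors whose simulation fails
(step-size underflow, non-finite or negative states) are discarded by
assigning a large penalty value instead of an error.

RMSE = sqrt(SSE / N) normalizes by the number of samples *per output* (N,
2781 for the artificial data), making the scale comparable to the measured
concentrations.  RMSEm applies the same root-mean normalization to the
distance between the full four-variable state trajectories of a candidate
and the reference model — it scores reconstruction of the hidden dynamics,
not just of the observed outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .data import Dataset
from .model import NEGATIVITY_TOL, StateTrajectory
from .observation import OutputMatrix

__all__ = [
    "PENALTY_VALUE",
    "ObjectiveContext",
    "sse",
    "rmse",
    "rmsem",
    "objective",
    "residuals",
    "InfeasibleParameters",
]

#: "Very high real value" assigned to infeasible candidates; exceeds any
#: attainable genuine SSE on the study's data by several orders of magnitude.
PENALTY_VALUE = 1e10


class InfeasibleParameters(RuntimeError):
    """Raised by :func:`residuals` when the candidate cannot be simulated."""


def sse(observed, predicted) -> float:
    """Sum of squared errors between two (M, N) output matrices."""
    a = observed.values if isinstance(observed, OutputMatrix) else np.asarray(observed, float)
    b = predicted.values if isinstance(predicted, OutputMatrix) else np.asarray(predicted, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.sum(d * d))


def rmse(sse_value: float, n_samples: int) -> float:
    """Root mean squared error: sqrt(SSE / N), N = samples per output."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return float(np.sqrt(sse_value / n_samples))


def rmsem(candidate: StateTrajectory, reference: StateTrajectory) -> float:
    """Root mean squared distance between two full state trajectories."""
    if candidate.times.shape != reference.times.shape or not np.allclose(
            candidate.times, reference.times):
        raise ValueError("trajectories must share the same time grid")
    d = candidate.states - reference.states
    return float(np.sqrt(np.sum(d * d) / candidate.times.size))


def _predict(scenario_name: str, states: np.ndarray) -> np.ndarray:
    """Prediction-map fast path on a raw (N, 4) state array -> (M, N)."""
    if scenario_name == "CO":
        return states.T
    if scenario_name in ("AO", "NPO"):
        return states[:, [1, 3]].T
    # TO
    return np.stack([states[:, 0] + states[:, 1], states[:, 2] + states[:, 3]])


@dataclass
class ObjectiveContext:
    """Everything a single objective evaluation needs, precomputed.

    Integration tolerances default to 1e-6 / 1e-9: looser than the
    simulation defaults because the objective is evaluated ~10^5 times per
    run and SSE is insensitive to local errors far below the noise floor.
    """

    dataset: Dataset
    penalty_value: float = PENALTY_VALUE
    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    max_steps: int = 20_000
    reference_trajectory: StateTrajectory | None = None
    n_outputs: int = field(init=False)

    def __post_init__(self):
        self._times = np.ascontiguousarray(self.dataset.times, dtype=float)
        self._observed = np.ascontiguousarray(self.dataset.observed, dtype=float)
        self._scenario_name = self.dataset.scenario.name
        self.n_outputs = self.dataset.scenario.n_outputs

    @property
    def n_samples(self) -> int:
        """Samples per output (the N of the RMSE normalization)."""
        return self._times.size

    def simulate_states(self, flat_params: np.ndarray) -> np.ndarray | None:
        """Integrate a candidate; returns the (N, 4) states or None if infeasible."""
        x = np.asarray(flat_params, dtype=float)
        status, states = _kernels.integrate(x[:18], x[18:], self._times,
                                            self.rel_tol, self.abs_tol,
                                            self.max_steps)
        if status != _kernels.STATUS_OK or not np.all(np.isfinite(states)):
            return None
        if np.any(states < -NEGATIVITY_TOL):
            return None
        np.clip(states, 0.0, None, out=states)
        return states

    def __call__(self, flat_params: np.ndarray) -> float:
        return objective(flat_params, self)


def objective(flat_params, ctx: ObjectiveContext) -> float:
    """Penalized SSE of a candidate parameter vector against the dataset."""
    states = ctx.simulate_states(flat_params)
    if states is None:
        return ctx.penalty_value
    d = _predict(ctx._scenario_name, states) - ctx._observed
    return float(np.sum(d * d))


def residuals(flat_params, ctx: ObjectiveContext) -> np.ndarray:
    """Flattened (observed - predicted) residual vector of length M*N.

    Raises :class:`InfeasibleParameters` on simulation failure (the local
    least-squares solver treats the restart as dead); the sum of squared
    residuals equals :func:`objective` for feasible candidates.
    """
    states = ctx.simulate_states(flat_params)
    if states is None:
        raise InfeasibleParameters("candidate parameters cannot be simulated")
    return (ctx._observed - _predict(ctx._scenario_name, states)).ravel()
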