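"""The Rab5-to-Rab7 cut-out switch ODE model and its simulation.

Endosome maturation is modeled as a bistable "cut-out switch" between the
Rab5 and Rab7 GTPase domains.  Each domain protein exists in an inactive
(``r5``, ``r7``) and an active, membrane-bound form (``R5``, ``R7``), all in
mol/l.  Ten reactions (constant production, sigmoidally gated activation,
Hill-type positive feedback on Rab7, and first-order decay/exchange) couple
the four species through 18 kinetic constants ``c1..c18``; together with the
four initial concentrations this gives a 22-dimensional parameter vector.

Simulated with the reference parameter values, the system sits in a
high-Rab5/low-Rab7 state for roughly the first 800 s and then switches
rapidly and irreversibly to the low-Rab5/high-Rab7 (mature endosome) state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "N_PARAMS",
    "IntegrationFailure",
    "NegativeState",
    "ParameterVector",
    "TimeGrid",
    "StateTrajectory",
    "reaction_rates",
    "ode_rhs",
    "simulate",
    "reference_parameters",
    "default_time_grid",
    "default_bounds",
]

PARAM_NAMES = tuple(f"c{i}" for i in range(1, 19)) + ("r5_0", "R5_0", "r7_0", "R7_0")
STATE_NAMES = ("r5", "R5", "r7", "R7")
N_PARAMS = 22

#: Published reference values of the kinetic constants (c1..c18) and the
#: initial concentrations (r5, R5, r7, R7 at t0).
_REFERENCE_VALUES = np.array([
    1.0, 0.3, 0.1, 2.5, 1.0, 0.483, 0.21, 3.0, 0.1, 0.021,
    1.0, 3.0, 0.31, 0.3, 3.0, 0.483, 0.06, 0.15,
    1.0, 0.001, 1.0, 0.001,
])

#: Open lower bounds are represented by a small positive epsilon.
BOUND_EPS = 1e-12

#: Sampled states in [-NEGATIVITY_TOL, 0) are clipped to zero; anything more
#: negative raises :class:`NegativeState`.
NEGATIVITY_TOL = 1e-9


class IntegrationFailure(RuntimeError):
    """The adaptive integrator could not complete the requested interval."""


class NegativeState(RuntimeError):
    """A sampled concentration fell below the negativity tolerance."""


def default_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Search-space bounds: c_i in (0, 4], initial concentrations in (0, 2]."""
    lower = np.full(N_PARAMS, BOUND_EPS)
    upper = np.concatenate([np.full(18, 4.0), np.full(4, 2.0)])
    return lower, upper


@dataclass(frozen=True)
class ParameterVector:
    """The 22-dimensional search point: c1..c18 plus four initial concentrations."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} parameters, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def kinetic_constants(self) -> np.ndarray:
        """c1..c18 as a length-18 array."""
        return self.values[:18]

    @property
    def initial_state(self) -> np.ndarray:
        """(r5, R5, r7, R7) at t0."""
        return self.values[18:]

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_NAMES.index(name)])

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterVector":
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        return cls(np.array([float(d[n]) for n in PARAM_NAMES]))

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterVector":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def within_bounds(self) -> bool:
        lower, upper = default_bounds()
        return bool(np.all(self.values > 0) and np.all(self.values <= upper)
                    and np.all(self.values >= lower))


@dataclass(frozen=True)
class TimeGrid:
    """A uniform sampling grid: ``n_points`` times spanning [t_start, t_end]."""

    t_start: float
    t_end: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.t_start, self.t_end, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.t_end - self.t_start) / (self.n_points - 1)


@dataclass
class StateTrajectory:
    """Sampled model states: times plus the four series r5, R5, r7, R7."""

    times: np.ndarray
    states: np.ndarray  # shape (N, 4), columns in STATE_NAMES order

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")

    def series(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, **{n: self.states[:, i] for i, n in enumerate(STATE_NAMES)}}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StateTrajectory":
        df = pd.read_csv(path)
        cols = ["time", *STATE_NAMES]
        if list(df.columns[:5]) != cols:
            raise ValueError(f"expected columns {cols}, got {list(df.columns)}")
        return cls(df["time"].to_numpy(), df[list(STATE_NAMES)].to_numpy())


def reference_parameters() -> ParameterVector:
    """The published reference parameter point of the cut-out switch model."""
    return ParameterVector(_REFERENCE_VALUES.copy())


def default_time_grid() -> TimeGrid:
    """The sampling grid of the pseudo-experimental data: 2781 points on [0, 1551] s."""
    return TimeGrid(0.0, 1551.0, 2781)


def _as_flat(params) -> np.ndarray:
    if isinstance(params, ParameterVector):
        return params.values
    arr = np.asarray(params, dtype=float)
    if arr.shape != (N_PARAMS,):
        raise ValueError(f"expected a {N_PARAMS}-vector, got shape {arr.shape}")
    return arr


def reaction_rates(state, t: float, params) -> np.ndarray:
    """The ten reaction rates v1..v10 at a given state and time.

    All rates are non-negative whenever the state is non-negative, t >= 0 and
    the parameters are positive; the sigmoid gates saturate rather than
    overflow for extreme arguments.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (4,):
        raise ValueError("state must be a 4-vector")
    if t < 0:
        raise ValueError("t must be >= 0")
    return _kernels.rates10(float(t), state, _as_flat(params)[:18])


def ode_rhs(state, t: float, params) -> np.ndarray:
    """Time derivatives of (r5, R5, r7, R7) under the switch kinetics."""
    state = np.asarray(state, dtype=float)
    if state.shape != (4,):
        raise ValueError("state must be a 4-vector")
    return _kernels.rhs(float(t), state, _as_flat(params)[:18])


def simulate(params, grid: TimeGrid | None = None, rel_tol: float = 1e-8,
             abs_tol: float = 1e-10, method: str = "rosenbrock") -> StateTrajectory:
    """Simulate the model from the initial concentrations stored in ``params``.

    Parameters
    ----------
    params : ParameterVector or 22-vector
        Kinetic constants and initial concentrations.
    grid : TimeGrid, optional
        Sampling grid; defaults to the 2781-point grid on [0, 1551] s.
    rel_tol, abs_tol : float
        Local error tolerances of the adaptive integrator.
    method : {"rosenbrock", "lsoda"}
        "rosenbrock" is the package's compiled adaptive ode23s scheme;
        "lsoda" routes through :func:`scipy.integrate.solve_ivp` and serves
        as an independent cross-check.

    Raises
    ------
    IntegrationFailure
        If the integrator cannot complete the interval.
    NegativeState
        If any sampled concentration falls below ``-NEGATIVITY_TOL``.
    """
    if grid is None:
        grid = default_time_grid()
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be positive")
    flat = _as_flat(params)
    t_eval = grid.times
    if method == "rosenbrock":
        status, states = _kernels.integrate(flat[:18], flat[18:], t_eval,
                                            rel_tol, abs_tol)
        if status != _kernels.STATUS_OK or not np.all(np.isfinite(states)):
            raise IntegrationFailure("adaptive step-size underflow or non-finite state")
    elif method == "lsoda":
        from scipy.integrate import solve_ivp

        c = flat[:18]
        sol = solve_ivp(lambda t, y: _kernels.rhs(t, y, c),
                        (t_eval[0], t_eval[-1]), flat[18:], method="LSODA",
                        t_eval=t_eval, rtol=rel_tol, atol=abs_tol)
        if not sol.success:
            raise IntegrationFailure(sol.message)
        states = sol.y.T
    else:
        raise ValueError(f"unknown integration method {method!r}")
    if np.any(states < -NEGATIVITY_TOL):
        raise NegativeState("sampled concentration below the negativity tolerance")
    np.clip(states, 0.0, None, out=states)
    return StateTrajectory(t_eval.copy(), states)
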