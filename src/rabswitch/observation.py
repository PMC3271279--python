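"""Observation scenarios: what a measurement reports about the hidden state.

Four scenarios map the full state (r5, R5, r7, R7) onto observed outputs:

* ``CO`` (complete): all four species are measured directly.
* ``AO`` (active-only): only the active forms R5 and R7 are measured.
* ``TO`` (totals): only the totals r5+R5 and r7+R7 are measured — the
  realistic fluorescence-measurement setting.
* ``NPO`` (neglect passive): the *data* are totals, but model predictions
  are taken to be the active forms only, i.e. the passive pools are
  (implausibly) neglected when matching model to data.

NPO is the one scenario whose data map and prediction map differ, which is
why a scenario carries both maps and :func:`observe` takes a ``role``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model import StateTrajectory

__all__ = ["ObservationScenario", "OutputMatrix", "SCENARIOS", "get_scenario", "observe"]


def _identity(states: np.ndarray) -> np.ndarray:
    return states.T.copy()


def _actives(states: np.ndarray) -> np.ndarray:
    return states[:, [1, 3]].T.copy()


def _totals(states: np.ndarray) -> np.ndarray:
    return np.stack([states[:, 0] + states[:, 1], states[:, 2] + states[:, 3]])


@dataclass(frozen=True)
class ObservationScenario:
    """A named observation scenario with separate data and prediction maps.

    Both maps take the ``(N, 4)`` state array of a trajectory and return an
    ``(M, N)`` output array.
    """

    name: str
    n_outputs: int
    data_map: Callable[[np.ndarray], np.ndarray]
    prediction_map: Callable[[np.ndarray], np.ndarray]

    @property
    def asymmetric(self) -> bool:
        return self.data_map is not self.prediction_map


SCENARIOS: dict[str, ObservationScenario] = {
    "co": ObservationScenario("CO", 4, _identity, _identity),
    "ao": ObservationScenario("AO", 2, _actives, _actives),
    "to": ObservationScenario("TO", 2, _totals, _totals),
    "npo": ObservationScenario("NPO", 2, _totals, _actives),
}


def get_scenario(name) -> ObservationScenario:
    """Look up a scenario by (case-insensitive) name; passes scenarios through."""
    if isinstance(name, ObservationScenario):
        return name
    key = str(name).lower()
    if key not in SCENARIOS:
        raise KeyError(f"unknown observation scenario {name!r}; "
                       f"choose from {sorted(SCENARIOS)}")
    return SCENARIOS[key]


@dataclass
class OutputMatrix:
    """Observed or predicted outputs: M concentration series over N times."""

    times: np.ndarray
    values: np.ndarray  # shape (M, N)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.times.size:
            raise ValueError("values must have one column per time point")

    @property
    def n_outputs(self) -> int:
        return self.values.shape[0]


def observe(traj: StateTrajectory, scenario, role: str = "data") -> OutputMatrix:
    """Apply a scenario's data or prediction map to a trajectory.

    ``role`` is ``"data"`` or ``"prediction"``; the two differ only for NPO.
    """
    sc = get_scenario(scenario)
    if role == "data":
        vals = sc.data_map(traj.states)
    elif role == "prediction":
        vals = sc.prediction_map(traj.states)
    else:
        raise ValueError("role must be 'data' or 'prediction'")
    return OutputMatrix(traj.times.copy(), vals)
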