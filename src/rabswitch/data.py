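"""Pseudo-experimental dataset generation and measured-data import.

The synthetic datasets emulate the study conditions: the reference model is
simulated on the 2781-point grid over [0, 1551] s, observed under one of the
four scenarios, and corrupted with multiplicative Gaussian noise
``Y_noisy = Y * (1 + s * N(0, 1))`` at relative noise levels s of 0, 5% or
20%.  Noisy values may legitimately be negative; the non-negativity
constraint applies to simulated concentrations, not to data.

Measured data (total Rab5 / total Rab7 time courses) can be read from plain
tabular files; their native time base can be aligned with the reference
simulation through the affine map ``t -> 4 t + 850``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ParameterVector, TimeGrid, simulate
from .observation import ObservationScenario, OutputMatrix, get_scenario, observe

__all__ = [
    "Dataset",
    "NOISE_LEVELS",
    "add_noise",
    "generate_dataset",
    "read_measured",
    "rescale_time",
]

#: The study's noise levels: noise-free, 5% and 20% relative noise.
NOISE_LEVELS = (0.0, 0.05, 0.2)


@dataclass
class Dataset:
    """An observed output matrix with its scenario and provenance metadata."""

    scenario: ObservationScenario
    times: np.ndarray
    observed: np.ndarray  # shape (M, N)
    noise_level: float
    seed: int | None = None
    provenance: str = "synthetic"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.observed = np.atleast_2d(np.asarray(self.observed, dtype=float))
        if self.observed.shape != (self.scenario.n_outputs, self.times.size):
            raise ValueError(
                f"observed must have shape (M={self.scenario.n_outputs}, "
                f"N={self.times.size}), got {self.observed.shape}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def n_times(self) -> int:
        return self.times.size

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write as CSV (time, y1..yM) plus a JSON metadata sidecar."""
        cols = {"time": self.times}
        for i in range(self.observed.shape[0]):
            cols[f"y{i + 1}"] = self.observed[i]
        pd.DataFrame(cols).to_csv(path, index=False)
        if sidecar:
            meta = {
                "scenario": self.scenario.name.lower(),
                "noise_level": self.noise_level,
                "seed": self.seed,
                "provenance": self.provenance,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        df = pd.read_csv(path)
        sc = get_scenario(meta["scenario"])
        obs = df[[f"y{i + 1}" for i in range(sc.n_outputs)]].to_numpy().T
        return cls(sc, df["time"].to_numpy(), obs, meta["noise_level"],
                   meta["seed"], meta["provenance"])


def add_noise(outputs: OutputMatrix, s: float, seed=None) -> OutputMatrix:
    """Apply multiplicative relative noise ``y -> y * (1 + s * N(0,1))``.

    Draws fill the (M, N) matrix in output-major (row-major) order, so a
    fixed seed reproduces the dataset bit-for-bit.  ``s = 0`` consumes no
    random draws and returns the values unchanged.
    """
    if s < 0:
        raise ValueError("noise level s must be >= 0")
    vals = outputs.values
    if s > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        vals = vals * (1.0 + s * rng.standard_normal(vals.shape))
    else:
        vals = vals.copy()
    return OutputMatrix(outputs.times.copy(), vals)


def generate_dataset(params, scenario, s: float, grid: TimeGrid | None = None,
                     seed=None, rel_tol: float = 1e-8, abs_tol: float = 1e-10) -> Dataset:
    """Simulate, observe (data role) and add noise: one pseudo-experimental dataset."""
    sc = get_scenario(scenario)
    if not isinstance(params, ParameterVector):
        params = ParameterVector(np.asarray(params, dtype=float))
    traj = simulate(params, grid, rel_tol=rel_tol, abs_tol=abs_tol)
    clean = observe(traj, sc, role="data")
    noisy = add_noise(clean, s, seed)
    return Dataset(sc, noisy.times, noisy.values, s,
                   seed if isinstance(seed, (int, np.integer)) else None, "synthetic")


def read_measured(path, scenario="to") -> Dataset:
    """Read a measured two-channel dataset (time, total Rab5, total Rab7).

    The file must be tabular (CSV or whitespace-delimited) with a time
    column followed by two output columns; times must be strictly
    increasing and are preserved verbatim (no resampling).  The scenario
    must be one of the two totals-based ones (TO or NPO).
    """
    sc = get_scenario(scenario)
    if sc.name not in ("TO", "NPO"):
        raise ValueError("measured data carry total concentrations; "
                         "scenario must be 'to' or 'npo'")
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise ValueError("expected a time column and two output columns")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    observed = df.iloc[:, 1:3].to_numpy(dtype=float).T
    return Dataset(sc, times, observed, 0.0, None, "measured")


def rescale_time(times) -> np.ndarray:
    """Map measured-data times onto the reference simulation time base (t -> 4t + 850)."""
    return 4.0 * np.asarray(times, dtype=float) + 850.0
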