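"""Monte-Carlo practical identifiability analysis.

Many replicate noisy datasets are generated from the reference model, the
estimator is re-run on each, and the resulting cloud of parameter estimates
is examined: replicates that produce an interquartile-fence outlier in any
parameter are dropped, and the retained subsample yields per-parameter
histograms (Freedman-Diaconis bin widths), percentile confidence intervals,
and a Pearson correlation matrix whose large off-diagonal entries expose
practically non-identifiable parameter combinations (e.g. the c1/c5
production/consumption trade-off of inactive Rab5).  Two-parameter slices
of the objective landscape visualize the same valleys directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, generate_dataset
from .model import PARAM_NAMES, ParameterVector, TimeGrid
from .objectives import ObjectiveContext, objective
from .optimizers import SearchBounds, run_method

__all__ = [
    "IdentifiabilityEnsemble",
    "ParameterReport",
    "mc_replicates",
    "mc_estimate",
    "flag_outliers",
    "fd_bin_width",
    "percentile_ci",
    "pearson",
    "correlation_matrix",
    "parameter_report",
    "objective_slice",
]


def mc_replicates(reference: ParameterVector, scenario, s: float,
                  grid: TimeGrid | None = None, n: int = 1000,
                  base_seed: int = 0) -> list[Dataset]:
    """n independently seeded noisy datasets from the reference trajectory."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_dataset(reference, scenario, s, grid, base_seed + k)
            for k in range(n)]


def flag_outliers(estimates) -> np.ndarray:
    """Mask of values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    v = np.asarray(estimates, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


def fd_bin_width(sample, fallback: float | None = None) -> float:
    """Freedman-Diaconis histogram bin width h = 2 IQR / n^(1/3).

    A zero-IQR sample has no natural width; ``fallback`` (default: the
    sample range or 1.0 if that is also zero) is returned instead.
    """
    v = np.asarray(sample, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr == 0.0:
        if fallback is not None:
            return fallback
        rng = float(v.max() - v.min())
        return rng if rng > 0 else 1.0
    return float(2.0 * iqr / v.size ** (1.0 / 3.0))


def percentile_ci(sample, level: float = 95.0) -> tuple[float, float, float]:
    """(low, high, length) percentile interval, linear interpolation."""
    v = np.asarray(sample, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    tail = (100.0 - level) / 2.0
    lo, hi = np.percentile(v, [tail, 100.0 - tail])
    return float(lo), float(hi), float(hi - lo)


def pearson(x, y) -> float:
    """Pearson correlation with population (1/N) standard deviations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length samples of size >= 2")
    n = x.size
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance")
    return float((np.dot(x, y) - n * mx * my) / (n * sx * sy))


@dataclass
class IdentifiabilityEnsemble:
    """Per-replicate estimates, the outlier mask, and the retained subsample."""

    estimates: np.ndarray           # (n_replicates, 22)
    objectives: np.ndarray          # best objective per replicate
    scenario: str
    noise_level: float
    outlier_mask: np.ndarray        # (n_replicates,) True = replicate dropped

    @property
    def retained(self) -> np.ndarray:
        return self.estimates[~self.outlier_mask]

    @property
    def n_retained(self) -> int:
        return int((~self.outlier_mask).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.estimates, columns=list(PARAM_NAMES))
        df["objective"] = self.objectives
        df["outlier"] = self.outlier_mask
        return df


def _retention_mask(estimates: np.ndarray) -> np.ndarray:
    """A replicate is dropped if any of its parameters is a fence outlier."""
    mask = np.zeros(estimates.shape[0], dtype=bool)
    for j in range(estimates.shape[1]):
        mask |= flag_outliers(estimates[:, j])
    return mask


def mc_estimate(datasets: list[Dataset], method: str = "de", budget: int = 500_000,
                base_seed: int = 0, config=None, rel_tol: float = 1e-6,
                abs_tol: float = 1e-9) -> IdentifiabilityEnsemble:
    """Re-estimate parameters on every replicate dataset and collect the cloud."""
    bounds = SearchBounds.default()
    n = len(datasets)
    estimates = np.empty((n, bounds.dim))
    objectives = np.empty(n)
    for k, ds in enumerate(datasets):
        ctx = ObjectiveContext(ds, rel_tol=rel_tol, abs_tol=abs_tol)
        from .objectives import residuals as _residuals

        res = run_method(method, ctx, bounds, budget, base_seed + k, config=config,
                         residuals_fn=lambda x: _residuals(x, ctx))
        estimates[k] = res.best_params
        objectives[k] = res.best_objective
    mask = _retention_mask(estimates)
    ds0 = datasets[0]
    return IdentifiabilityEnsemble(estimates, objectives, ds0.scenario.name,
                                   ds0.noise_level, mask)


def correlation_matrix(ensemble: IdentifiabilityEnsemble) -> pd.DataFrame:
    """22 x 22 Pearson correlation matrix of the retained subsample.

    Parameters with zero variance across the subsample get NaN off-diagonal
    entries (their correlation is undefined) and 1 on the diagonal.
    """
    ret = ensemble.retained
    p = ret.shape[1]
    mat = np.full((p, p), np.nan)
    np.fill_diagonal(mat, 1.0)
    stds = ret.std(axis=0)
    for i in range(p):
        for j in range(i + 1, p):
            if stds[i] > 0 and stds[j] > 0:
                mat[i, j] = mat[j, i] = pearson(ret[:, i], ret[:, j])
    return pd.DataFrame(mat, index=list(PARAM_NAMES), columns=list(PARAM_NAMES))


@dataclass
class ParameterReport:
    name: str
    mean: float
    std: float
    ci_low: float
    ci_high: float
    ci_length: float
    bin_width: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray


def parameter_report(ensemble: IdentifiabilityEnsemble, name: str) -> ParameterReport:
    """Histogram, moments and 95% percentile CI of one parameter's estimates."""
    j = PARAM_NAMES.index(name)
    v = ensemble.retained[:, j]
    lo, hi, length = percentile_ci(v)
    h = fd_bin_width(v)
    span = v.max() - v.min()
    n_bins = max(1, int(np.ceil(span / h))) if span > 0 else 1
    counts, edges = np.histogram(v, bins=n_bins)
    return ParameterReport(name, float(v.mean()), float(v.std()), lo, hi, length,
                           h, counts, edges)


def objective_slice(ctx: ObjectiveContext, base: ParameterVector, dim_i, dim_j,
                    grid_resolution: int = 25,
                    bounds: SearchBounds | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Objective on a 2-D lattice over two parameters, others fixed at ``base``.

    Returns (xs, ys, Z) with Z[a, b] the objective at dim_i = xs[a],
    dim_j = ys[b]; simulation failures appear as the penalty value.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    bounds = bounds or SearchBounds.default()
    i = PARAM_NAMES.index(dim_i) if isinstance(dim_i, str) else int(dim_i)
    j = PARAM_NAMES.index(dim_j) if isinstance(dim_j, str) else int(dim_j)
    if i == j:
        raise ValueError("dims must be distinct")
    xs = np.linspace(bounds.lower[i], bounds.upper[i], grid_resolution)
    ys = np.linspace(bounds.lower[j], bounds.upper[j], grid_resolution)
    Z = np.empty((grid_resolution, grid_resolution))
    x = base.values.copy()
    for a, xa in enumerate(xs):
        for b, yb in enumerate(ys):
            x[i] = xa
            x[j] = yb
            Z[a, b] = objective(x, ctx)
    return xs, ys, Z
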