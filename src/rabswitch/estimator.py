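"""scikit-learn style front end for kinetic parameter estimation.

`SwitchKineticsEstimator` wraps the whole pipeline — observation scenario,
penalized SSE objective, and one of the four optimizers — behind the
familiar ``fit(X, y)`` / ``predict(X)`` interface, so the estimator
composes with sklearn model selection and pipelines.  ``X`` is the sample
times (seconds) and ``y`` the observed outputs, one column per output
channel of the scenario.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import Dataset
from .model import ParameterVector, simulate
from .objectives import ObjectiveContext, residuals, rmse
from .observation import get_scenario, observe
from .optimizers import SearchBounds, run_method

__all__ = ["SwitchKineticsEstimator"]


class SwitchKineticsEstimator(RegressorMixin, BaseEstimator):
    """Estimate cut-out switch kinetics from observed time courses.

    Parameters
    ----------
    scenario : str, default "co"
        Observation scenario ("co", "ao", "to" or "npo"); determines how
        many output columns ``y`` must have and which model quantities the
        predictions report.
    method : str, default "de"
        Optimizer: "de", "pso", "dasa" or "a717" (restarted local least
        squares).
    budget : int, default 50_000
        Objective-evaluation budget of the fit.
    config : optional
        Method-specific configuration object; defaults to the tuned
        settings.
    rel_tol, abs_tol : float
        Integration tolerances used inside the objective.
    seed : int or None
        Seed for the optimizer's randomness.

    Attributes
    ----------
    parameters_ : ParameterVector
        The fitted 22-dimensional parameter point.
    objective_ : float
        Final (best) penalized SSE.
    rmse_ : float
        sqrt(objective_ / n_samples).
    result_ : OptimizerResult
        Full optimizer output including the convergence trace.
    """

    def __init__(self, scenario: str = "co", method: str = "de",
                 budget: int = 50_000, config=None, rel_tol: float = 1e-6,
                 abs_tol: float = 1e-9, seed: int | None = None):
        self.scenario = scenario
        self.method = method
        self.budget = budget
        self.config = config
        self.rel_tol = rel_tol
        self.abs_tol = abs_tol
        self.seed = seed

    def _validate_times(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be the sample times: shape (N,) or (N, 1)")
            X = X[:, 0]
        if X.ndim != 1 or X.size < 2:
            raise ValueError("need at least two sample times")
        if np.any(np.diff(X) <= 0):
            raise ValueError("times must be strictly increasing")
        return X

    def fit(self, X, y):
        """Fit the 22 kinetic parameters to observed outputs.

        ``X`` holds the N sample times; ``y`` is (N, M) with M the
        scenario's output count (a 1-D y is accepted for M = 1 scenarios —
        none of the built-in ones, so y is effectively always 2-D).
        """
        times = self._validate_times(X)
        sc = get_scenario(self.scenario)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape != (times.size, sc.n_outputs):
            raise ValueError(f"y must have shape (N={times.size}, "
                             f"M={sc.n_outputs}) for scenario {sc.name}")
        dataset = Dataset(sc, times, y.T, 0.0, None, "user")
        ctx = ObjectiveContext(dataset, rel_tol=self.rel_tol, abs_tol=self.abs_tol)
        res = run_method(self.method, ctx, SearchBounds.default(), self.budget,
                         self.seed, config=self.config,
                         residuals_fn=lambda x: residuals(x, ctx))
        self.n_features_in_ = 1
        self.result_ = res
        self.parameters_ = ParameterVector(res.best_params)
        self.objective_ = res.best_objective
        self.rmse_ = rmse(res.best_objective, ctx.n_samples)
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted outputs (N, M) at times ``X`` under the fitted parameters."""
        check_is_fitted(self, "parameters_")
        times = self._validate_times(X)
        from .model import StateTrajectory
        from . import _kernels

        flat = self.parameters_.values
        status, states = _kernels.integrate(flat[:18], flat[18:],
                                            np.ascontiguousarray(times),
                                            self.rel_tol, self.abs_tol)
        if status != _kernels.STATUS_OK:
            raise RuntimeError("integration failed at the fitted parameters")
        traj = StateTrajectory(times, np.clip(states, 0.0, None))
        return observe(traj, self.scenario, role="prediction").values.T
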