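"""Bound-constrained minimizers used for kinetic parameter estimation.

Four methods share one contract: minimize a callable objective over box
bounds under a fixed budget of objective evaluations, with full
reproducibility given a seed, and return the best point, its objective and
an evaluation-indexed best-so-far trace.

* :func:`run_de` — classic generational differential evolution with the ten
  named DE/x/y/z strategies and bound clipping.
* :func:`run_pso` — standard particle swarm with random informant topology
  and hypersphere sampling around a center of gravity.
* :func:`run_dasa` — the differential ant-stigmergy algorithm: ants walk a
  layered graph of discretized per-parameter offsets whose pheromone is a
  per-parameter Cauchy density, with restart on stagnation.
* :func:`run_local_restarts` — a restarted local trust-region nonlinear
  least-squares descent (scipy's TRF with finite-difference derivatives),
  the derivative-based baseline; a global method it is not.

Tuned defaults follow the study's settings: DE strategy 8
("DE/rand-to-best/1/bin"), P=81, F=0.942, CR=0.915; PSO S=155, K=89,
w=0.762, c=1.037; DASA m=144, rho=0.036, s+=0.575, s-=0.01, b=10, eps=1e-15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import default_bounds
from .objectives import PENALTY_VALUE, InfeasibleParameters

__all__ = [
    "SearchBounds",
    "ConvergenceTrace",
    "OptimizerResult",
    "DEConfig",
    "PSOConfig",
    "DASAConfig",
    "DE_STRATEGY_NAMES",
    "clip_to_bounds",
    "de_mutant",
    "de_crossover",
    "run_de",
    "run_pso",
    "dasa_build_graph",
    "run_dasa",
    "run_local_restarts",
    "run_method",
    "METHODS",
]

DEFAULT_BUDGET = 500_000

DE_STRATEGY_NAMES = {
    1: "DE/best/1/exp", 2: "DE/rand/1/exp", 3: "DE/rand-to-best/1/exp",
    4: "DE/best/2/exp", 5: "DE/rand/2/exp", 6: "DE/best/1/bin",
    7: "DE/rand/1/bin", 8: "DE/rand-to-best/1/bin", 9: "DE/best/2/bin",
    10: "DE/rand/2/bin",
}


@dataclass(frozen=True)
class SearchBounds:
    """Box constraints; open lower bounds carry a small positive epsilon."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        if lo.shape != up.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if np.any(lo >= up):
            raise ValueError("lower must be < upper componentwise")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @classmethod
    def default(cls) -> "SearchBounds":
        """The 22-dimensional model search space: (0, 4]^18 x (0, 2]^4."""
        return cls(*default_bounds())

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        size = self.dim if n is None else (n, self.dim)
        return rng.uniform(self.lower, self.upper, size)


def clip_to_bounds(point: np.ndarray, bounds: SearchBounds) -> np.ndarray:
    """Clamp each coordinate to the closest range limit."""
    return np.clip(point, bounds.lower, bounds.upper)


@dataclass
class ConvergenceTrace:
    """Best-so-far objective indexed by evaluation count (improvements only)."""

    evaluations: np.ndarray
    best: np.ndarray

    def best_at(self, n_evals: int) -> float:
        """Best objective seen within the first ``n_evals`` evaluations."""
        i = np.searchsorted(self.evaluations, n_evals, side="right") - 1
        if i < 0:
            return math.inf
        return float(self.best[i])


@dataclass
class OptimizerResult:
    best_params: np.ndarray
    best_objective: float
    trace: ConvergenceTrace
    evaluations_used: int
    seed: int | None


class BudgetExhausted(RuntimeError):
    """Internal: an evaluation was requested beyond the budget."""


class _Counter:
    """Counts evaluations, tracks the incumbent and records the trace."""

    def __init__(self, fn, budget: int):
        self.fn = fn
        self.budget = int(budget)
        self.n = 0
        self.best_f = math.inf
        self.best_x: np.ndarray | None = None
        self._ev: list[int] = []
        self._bf: list[float] = []

    @property
    def remaining(self) -> int:
        return self.budget - self.n

    def submit_value(self, f: float, x: np.ndarray) -> None:
        if self.n >= self.budget:
            raise BudgetExhausted
        self.n += 1
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x, dtype=float, copy=True)
            self._ev.append(self.n)
            self._bf.append(float(f))

    def __call__(self, x: np.ndarray) -> float:
        if self.n >= self.budget:
            raise BudgetExhausted
        f = float(self.fn(x))
        self.submit_value(f, x)
        return f

    def result(self, seed, fallback_x: np.ndarray) -> OptimizerResult:
        best_x = self.best_x if self.best_x is not None else np.array(fallback_x, float)
        best_f = self.best_f if self.best_x is not None else PENALTY_VALUE
        trace = ConvergenceTrace(np.array(self._ev, dtype=np.int64),
                                 np.array(self._bf, dtype=float))
        return OptimizerResult(best_x, float(best_f), trace, self.n, seed)


# ---------------------------------------------------------------------------
# Differential evolution

@dataclass(frozen=True)
class DEConfig:
    population: int = 81
    strategy: int = 8
    weight: float = 0.942
    crossover: float = 0.915

    def __post_init__(self):
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.strategy not in DE_STRATEGY_NAMES:
            raise ValueError("strategy must be in 1..10")
        if not 0.0 <= self.weight <= 2.0:
            raise ValueError("weight F must be in [0, 2]")
        if not 0.0 <= self.crossover <= 1.0:
            raise ValueError("crossover CR must be in [0, 1]")


# parents drawn at random (beyond best/candidate) per strategy
_DE_N_RAND = {1: 2, 2: 3, 3: 2, 4: 4, 5: 5, 6: 2, 7: 3, 8: 2, 9: 4, 10: 5}


def de_mutant(population: np.ndarray, candidate_index: int, best_index,
              F: float, strategy: int, rng: np.random.Generator) -> np.ndarray:
    """Differential mutant for the given DE/x/y strategy (1..10).

    ``best_index`` may be an index into the population or the best vector
    itself (the generational loop passes the live best-so-far member).
    """
    if strategy not in DE_STRATEGY_NAMES:
        raise ValueError("strategy must be in 1..10")
    P = population.shape[0]
    need = _DE_N_RAND[strategy]
    if P < need + 1:
        raise ValueError(f"population too small for strategy {strategy}")
    pool = np.delete(np.arange(P), candidate_index)
    r = rng.choice(pool, size=need, replace=False)
    x = population
    best = x[best_index] if np.isscalar(best_index) else np.asarray(best_index)
    base = strategy if strategy <= 5 else strategy - 5
    if base == 1:      # best/1
        return best + F * (x[r[0]] - x[r[1]])
    if base == 2:      # rand/1
        return x[r[0]] + F * (x[r[1]] - x[r[2]])
    if base == 3:      # rand-to-best/1
        xc = x[candidate_index]
        return xc + F * (best - xc) + F * (x[r[0]] - x[r[1]])
    if base == 4:      # best/2
        return best + F * (x[r[0]] + x[r[1]] - x[r[2]] - x[r[3]])
    # rand/2
    return x[r[4]] + F * (x[r[0]] + x[r[1]] - x[r[2]] - x[r[3]])


def de_crossover(candidate: np.ndarray, mutant: np.ndarray, CR: float,
                 kind: str, rng: np.random.Generator) -> np.ndarray:
    """Binomial or exponential crossover with one guaranteed mutant coordinate."""
    if not 0.0 <= CR <= 1.0:
        raise ValueError("CR must be in [0, 1]")
    D = candidate.size
    trial = candidate.copy()
    if kind == "bin":
        mask = rng.random(D) < CR
        mask[rng.integers(D)] = True
        trial[mask] = mutant[mask]
    elif kind == "exp":
        start = rng.integers(D)
        length = 1
        while length < D and rng.random() < CR:
            length += 1
        idx = (start + np.arange(length)) % D
        trial[idx] = mutant[idx]
    else:
        raise ValueError("kind must be 'bin' or 'exp'")
    return trial


def run_de(objective, bounds: SearchBounds, config: DEConfig | None = None,
           budget: int = DEFAULT_BUDGET, seed: int | None = None) -> OptimizerResult:
    """Classic generational DE: mutate, crossover, clip, greedy replacement."""
    config = config or DEConfig()
    rng = np.random.default_rng(seed)
    counter = _Counter(objective, budget)
    P = config.population
    kind = "exp" if config.strategy <= 5 else "bin"
    pop = bounds.sample(rng, P)
    fit = np.full(P, math.inf)
    try:
        for i in range(P):
            fit[i] = counter(pop[i])
        best_vec = pop[int(np.argmin(fit))].copy()
        best_val = float(np.min(fit))
        while True:
            new_pop = pop.copy()
            new_fit = fit.copy()
            for i in range(P):
                mutant = de_mutant(pop, i, best_vec, config.weight,
                                   config.strategy, rng)
                trial = de_crossover(pop[i], mutant, config.crossover, kind, rng)
                trial = clip_to_bounds(trial, bounds)
                f = counter(trial)
                if f <= fit[i]:
                    new_pop[i] = trial
                    new_fit[i] = f
                    if f < best_val:  # live best, as in the classic scheme
                        best_val = f
                        best_vec = trial.copy()
            pop, fit = new_pop, new_fit
    except BudgetExhausted:
        pass
    return counter.result(seed, pop[0])


# ---------------------------------------------------------------------------
# Particle swarm

@dataclass(frozen=True)
class PSOConfig:
    swarm: int = 155
    neighborhood: int = 89
    inertia: float = 0.762
    acceleration: float = 1.037

    def __post_init__(self):
        if self.swarm < 2:
            raise ValueError("swarm must be >= 2")
        if not 1 <= self.neighborhood <= self.swarm - 1:
            raise ValueError("neighborhood K must satisfy 1 <= K <= S-1")


def _pso_links(rng: np.random.Generator, S: int, K: int) -> list[np.ndarray]:
    """Each particle's informant set: itself plus K distinct random others."""
    links = []
    for i in range(S):
        pool = np.delete(np.arange(S), i)
        links.append(np.append(rng.choice(pool, size=K, replace=False), i))
    return links


def _sample_hypersphere(rng: np.random.Generator, center: np.ndarray,
                        radius: float) -> np.ndarray:
    """Random point inside the ball: uniform direction, radius ~ U(0, r).

    The radial-uniform law concentrates samples near the center; the
    volume-uniform alternative puts nearly all mass at the surface in 22
    dimensions, where a random surface direction is almost orthogonal to
    the improvement direction and the swarm stalls.
    """
    D = center.size
    direction = rng.standard_normal(D)
    norm = np.linalg.norm(direction)
    if norm == 0.0 or radius == 0.0:
        return center.copy()
    return center + (radius * rng.random() / norm) * direction


def run_pso(objective, bounds: SearchBounds, config: PSOConfig | None = None,
            budget: int = DEFAULT_BUDGET, seed: int | None = None) -> OptimizerResult:
    """Standard PSO with hypersphere sampling and variable random topology.

    The center of gravity is g = x + c*((p-x)+(l-x))/3 (g = x + c*(p-x)/2
    when the particle is its own best informant); the new velocity is
    w*v plus a displacement toward a uniform sample of the ball centered at
    g with radius ||g - x||.  Informant links are redrawn after an iteration
    that fails to improve the swarm best.
    """
    config = config or PSOConfig()
    rng = np.random.default_rng(seed)
    counter = _Counter(objective, budget)
    S, K = config.swarm, config.neighborhood
    w, c = config.inertia, config.acceleration
    x = bounds.sample(rng, S)
    v = (bounds.sample(rng, S) - x) / 2.0
    fit = np.full(S, math.inf)
    try:
        for i in range(S):
            fit[i] = counter(x[i])
        pbest = x.copy()
        pbest_f = fit.copy()
        links = _pso_links(rng, S, K)
        swarm_best = float(np.min(pbest_f))
        while True:
            for i in range(S):
                informants = links[i]
                l = informants[int(np.argmin(pbest_f[informants]))]
                p = pbest[i]
                if l == i:
                    g = x[i] + c * (p - x[i]) / 2.0
                else:
                    g = x[i] + c * ((p - x[i]) + (pbest[l] - x[i])) / 3.0
                radius = float(np.linalg.norm(g - x[i]))
                target = _sample_hypersphere(rng, g, radius)
                v[i] = w * v[i] + (target - x[i])
                xi = x[i] + v[i]
                clipped = clip_to_bounds(xi, bounds)
                v[i][clipped != xi] = 0.0
                x[i] = clipped
                f = counter(x[i])
                if f < pbest_f[i]:
                    pbest_f[i] = f
                    pbest[i] = x[i].copy()
            new_best = float(np.min(pbest_f))
            if new_best >= swarm_best:
                links = _pso_links(rng, S, K)
            swarm_best = min(swarm_best, new_best)
    except BudgetExhausted:
        pass
    return counter.result(seed, x[0])


# ---------------------------------------------------------------------------
# Differential ant-stigmergy algorithm

@dataclass(frozen=True)
class DASAConfig:
    ants: int = 144
    evaporation: float = 0.036
    scale_increase: float = 0.575
    scale_decrease: float = 0.01
    base: int = 10
    precision: float = 1e-15

    def __post_init__(self):
        if self.ants < 1:
            raise ValueError("ants must be >= 1")
        if not 0.0 < self.scale_decrease <= self.evaporation < 1.0:
            raise ValueError("need 0 < s_minus <= rho < 1")
        if self.base < 2:
            raise ValueError("base must be >= 2")
        if self.precision <= 0:
            raise ValueError("precision must be > 0")


def dasa_build_graph(bounds: SearchBounds, base: int = 10,
                     precision: float = 1e-15) -> list[np.ndarray]:
    """Per-parameter offset catalogues {0} U {+-b^k : k_min..k_max}.

    k_min = floor(log_b precision) and k_max = ceil(log_b width), so the
    offsets span the minimal resolvable change up to the parameter's full
    range width; offsets are sorted ascending with 0 in the middle.
    """
    if base < 2 or precision <= 0:
        raise ValueError("need base >= 2 and precision > 0")
    catalogues = []
    for width in bounds.width:
        kmin = math.floor(math.log(precision, base))
        kmax = math.ceil(math.log(width, base))
        mags = np.array([float(base) ** k for k in range(kmin, kmax + 1)])
        catalogues.append(np.concatenate([-mags[::-1], [0.0], mags]))
    return catalogues


def _cauchy_masses(offsets: np.ndarray, loc: float, scale: float) -> np.ndarray:
    """Pheromone of each vertex: the Cauchy density at its offset, normalized.

    Evaluating the density *at* the vertex offsets gives the zero vertex
    (and the near-zero magnitudes) the bulk of the mass when the density is
    centered at the origin, so a typical ant path perturbs only a few
    parameters substantially -- and all-zero paths become near-certain as
    the scale collapses, which is what arms the stagnation restart.
    """
    masses = 1.0 / (1.0 + ((offsets - loc) / scale) ** 2)
    total = masses.sum()
    if total <= 0 or not np.isfinite(total):
        return np.full(offsets.size, 1.0 / offsets.size)
    return masses / total


def run_dasa(objective, bounds: SearchBounds, config: DASAConfig | None = None,
             budget: int = DEFAULT_BUDGET, seed: int | None = None) -> OptimizerResult:
    """Differential ant-stigmergy search with Cauchy pheromone densities.

    Each of m ants draws one offset per parameter layer with probability
    proportional to the Cauchy pheromone density at the offset; the candidate
    is the clipped sum of the temporary best and the offsets.  Improvement
    moves the temporary best and the Cauchy locations to the winning
    offsets and stretches the scales by (1 + s_plus); failure shrinks the
    scales by (1 - s_minus) and decays the locations by (1 - rho).  After
    D^2 consecutive all-zero-offset iterations the search restarts from a
    uniform random point with reinitialized densities; the global best over
    restarts is returned.
    """
    config = config or DASAConfig()
    rng = np.random.default_rng(seed)
    counter = _Counter(objective, budget)
    D = bounds.dim
    m = config.ants
    catalogues = dasa_build_graph(bounds, config.base, config.precision)
    offsets = catalogues[0]
    same_catalogue = all(np.array_equal(cat, offsets) for cat in catalogues)
    widths = bounds.width

    def fresh_pdfs():
        return np.zeros(D), np.ones(D)

    x_tb = bounds.sample(rng)
    loc, scale = fresh_pdfs()
    stagnation = 0
    try:
        f_tb = counter(x_tb)
        while True:
            # per-dimension pheromone masses and ant draws
            draws = np.empty((m, D))
            all_zero = True
            for d in range(D):
                cat = offsets if same_catalogue else catalogues[d]
                masses = _cauchy_masses(cat, loc[d], scale[d])
                idx = np.searchsorted(np.cumsum(masses), rng.random(m), side="right")
                idx = np.minimum(idx, cat.size - 1)
                draws[:, d] = cat[idx]
            if np.any(draws != 0.0):
                all_zero = False
            best_ant_f = math.inf
            best_ant = None
            for a in range(m):
                cand = clip_to_bounds(x_tb + draws[a], bounds)
                f = counter(cand)
                if f < best_ant_f:
                    best_ant_f = f
                    best_ant = a
            if best_ant is not None and best_ant_f < f_tb:
                f_tb = best_ant_f
                x_tb = clip_to_bounds(x_tb + draws[best_ant], bounds)
                loc = draws[best_ant].copy()
                scale = np.minimum(scale * (1.0 + config.scale_increase), widths)
            else:
                scale = np.maximum(scale * (1.0 - config.scale_decrease),
                                   config.precision)
                loc *= (1.0 - config.evaporation)
            stagnation = stagnation + 1 if all_zero else 0
            if stagnation >= D * D:
                x_tb = bounds.sample(rng)
                f_tb = counter(x_tb)
                loc, scale = fresh_pdfs()
                stagnation = 0
    except BudgetExhausted:
        pass
    return counter.result(seed, x_tb)


# ---------------------------------------------------------------------------
# Restarted local least squares

class _RestartAbort(RuntimeError):
    pass


def run_local_restarts(objective, residuals_fn, bounds: SearchBounds,
                       n_restarts: int = 20_000, evals_per_restart: int = 25,
                       seed: int | None = None) -> OptimizerResult:
    """Random-restart bound-constrained trust-region nonlinear least squares.

    Each restart draws a uniform random point and runs scipy's TRF solver on
    the residual vector with finite-difference derivatives, capped at
    ``evals_per_restart`` objective evaluations (derivative evaluations
    count).  A restart whose residual evaluation fails is abandoned; the
    failed evaluation is charged at the penalty value.  The global best over
    restarts is returned; if nothing was feasible the result carries the
    penalty objective.
    """
    from scipy.optimize import least_squares

    rng = np.random.default_rng(seed)
    budget = n_restarts * evals_per_restart
    counter = _Counter(objective, budget)
    x0 = bounds.sample(rng)
    for _ in range(n_restarts):
        if counter.remaining <= 0:
            break
        x0 = bounds.sample(rng)
        cap = min(evals_per_restart, counter.remaining)
        used_here = 0

        def fun(x):
            nonlocal used_here
            if used_here >= cap:
                raise _RestartAbort
            used_here += 1
            try:
                r = residuals_fn(x)
            except InfeasibleParameters:
                counter.submit_value(PENALTY_VALUE, x)
                raise _RestartAbort
            counter.submit_value(float(np.dot(r, r)), x)
            return r

        try:
            least_squares(fun, x0, bounds=(bounds.lower, bounds.upper),
                          method="trf", jac="2-point", max_nfev=max(cap, 1))
        except (_RestartAbort, BudgetExhausted):
            continue
    return counter.result(seed, x0)


# ---------------------------------------------------------------------------
# Dispatch

METHODS = ("dasa", "pso", "de", "a717")


def run_method(name: str, objective, bounds: SearchBounds, budget: int,
               seed: int | None = None, config=None, residuals_fn=None) -> OptimizerResult:
    """Run one of the four methods by name ('de', 'pso', 'dasa', 'a717')."""
    key = name.lower()
    if key == "de":
        return run_de(objective, bounds, config, budget, seed)
    if key == "pso":
        return run_pso(objective, bounds, config, budget, seed)
    if key == "dasa":
        return run_dasa(objective, bounds, config, budget, seed)
    if key in ("a717", "local"):
        if residuals_fn is None:
            raise ValueError("the local least-squares method needs residuals_fn")
        evals_per_restart = 25
        n_restarts = max(1, budget // evals_per_restart)
        return run_local_restarts(objective, residuals_fn, bounds,
                                  n_restarts, evals_per_restart, seed)
    raise ValueError(f"unknown method {name!r}; choose from {METHODS}")
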