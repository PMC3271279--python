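# Methods

## The model

Endosome maturation is represented as a cut-out switch between the Rab5 and
Rab7 GTPase domains.  Four species are tracked, all in mol/l: inactive and
active Rab5 (`r5`, `R5`) and inactive and active Rab7 (`r7`, `R7`).  Ten
reactions couple them:

    v1  = c1                                        constant r5 production
    v2  = c2 r5 / (1 + e^{(c3 - R5) c4}) · t/(100+t)  gated Rab5 activation
    v3  = c5 r5                                     r5 turnover
    v4  = c6                                        constant r7 production
    v5  = c7 r7 R7^c8 / (c9 + R7^c8)                Hill-type Rab7 activation
    v6  = c10 r7 / (1 + e^{(c11 - R5) c12})         Rab5-gated Rab7 activation
    v7  = c13 R5 / (1 + e^{(c14 - R7) c15})         Rab7-gated Rab5 deactivation
    v8  = c16 r7,  v9 = c17 R5,  v10 = c18 R7       first-order decay/exchange

    dr5/dt = v1 + v7 + v9 - v2 - v3     dR5/dt = v2 - v7 - v9
    dr7/dt = v4 + v10 - v5 - v6 - v8    dR7/dt = v5 + v6 - v10

Two algebraic identities follow immediately and are enforced as exact tests:
d(r5+R5)/dt = v1 − v3 and d(r7+R7)/dt = v4 − v8.  With positive parameters
the non-negative orthant is invariant (every sink of a species is
proportional to that species), so negative sampled states can only be
numerical artifacts; values in [−1e−9, 0) are clipped to zero and anything
below that raises `NegativeState`.

The reference parameter point is `c = (1, 0.3, 0.1, 2.5, 1, 0.483, 0.21, 3,
0.1, 0.021, 1, 3, 0.31, 0.3, 3, 0.483, 0.06, 0.15)` with initial state
`(1, 0.001, 1, 0.001)`.  Simulated over [0, 1551] s it stays in the
high-Rab5 state for ~800 s, then switches rapidly and irreversibly to the
high-Rab7 state while the inactive pools barely move.

The estimation problem is 22-dimensional: the 18 kinetic constants, bounded
in (0, 4], plus the four initial concentrations, bounded in (0, 2].  Open
lower bounds are represented by the epsilon 1e−12.

## Integration

The default integrator is a compiled (numba) adaptive second-order
Rosenbrock scheme — the classic ode23s pair: L-stable, one analytic 4×4
Jacobian factorization and three linear solves per step — with cubic-Hermite
dense output at the requested sample times and elementwise error control
against `atol + rtol·|y|`.  Defaults are rtol 1e−8 / atol 1e−10 for
simulation and data generation, and rtol 1e−6 / atol 1e−9 inside the
estimation objective, where the SSE is insensitive to local errors far
below the data scale and each run performs 10^4–10^5 integrations.  A step
cap (20 000 step attempts inside the objective, 500 000 for plain
simulation) converts near-stagnating integrations — which some infeasible
parameter combinations provoke — into fast failures; failures of any kind
(step underflow, non-finite state, cap, negative concentrations) are mapped
to the penalty value 1e10 by the objective, i.e. the candidate is discarded.

scipy's LSODA is available as `simulate(..., method="lsoda")` and serves as
an independent cross-check: on the reference trajectory the two integrators
agree to a maximal relative difference of ~2e−5 at tight tolerances, and
halving the tolerances changes the default solution by less than 1e−4
relative (both are regression tests).

The sigmoid gates clamp their exponent arguments to ±700 so extreme
parameters saturate the gate instead of overflowing; the Hill term uses
max(R7, 0) so transient tiny negatives under non-integer exponents cannot
produce NaNs.

## Observation scenarios and objective

Four observation maps connect hidden states to data: CO (all four states),
AO (actives R5, R7), TO (totals r5+R5, r7+R7 — the realistic measurement)
and NPO (data are totals but predictions are actives; the deliberately
inconsistent convention of the original modeling work).  A scenario object
carries separate data and prediction maps; they differ only for NPO, which
is why the reference point scores SSE ≈ 5549.85 under NPO on noise-free
data (the SSE reduces to Σ r5² + r7² over the grid) while CO/AO/TO score
exactly zero.

The fit objective is the plain SSE between observed and predicted outputs.
RMSE = sqrt(SSE/N) uses N = samples per output (2781 for artificial data),
a convention fixed by internal consistency of the reference-point table
(0.031 = sqrt(2.653/2781)).  RMSEm applies the same normalization to the
distance between full four-variable state trajectories and measures
reconstruction of the hidden dynamics.

## Synthetic data

Artificial datasets are the reference trajectory sampled at 2781 equally
spaced points on [0, 1551] s (read as inclusive endpoints, spacing
1551/2780), observed under a scenario's data map, with multiplicative
noise `y → y (1 + s·N(0,1))` at s ∈ {0, 0.05, 0.2}.  Draws fill the M×N
output matrix in row-major order from one seeded generator per dataset, so
datasets are bit-reproducible.  Noisy values may be negative; the
non-negativity constraint applies to simulated concentrations, not data.
What this generator deliberately does not emulate: the manual alignment,
scaling and averaging of individual endosome traces behind the real
measurements, autocorrelated measurement error, and irregular sampling.
Passing tests therefore demonstrate correctness of the pipeline under the
stated noise model, not robustness to real measurement artifacts.
Measured two-channel files (time, total Rab5, total Rab7) are read
verbatim; the affine map t → 4t + 850 aligns their conversion-centered time
base with the reference simulation.

## Optimizers

All four methods minimize a counted objective under box bounds with a fixed
evaluation budget and seeded randomness; out-of-bounds proposals are set to
the closest range limit.

**DE** is the classic generational scheme with the ten named strategies
("DE/best/1/exp" … "DE/rand/2/bin"); the tuned default is strategy 8,
"DE/rand-to-best/1/bin", P = 81, F = 0.942, CR = 0.915.  The best member
used by *-to-best mutation is updated immediately when a trial improves on
it, as in the classic reference code.  The printed sources conflict on
which of 0.942/0.915 is F and which CR; the tuning-table column order is
followed, and both are configurable.

**PSO** is the standard hypersphere variant: each particle has K random
informants (plus itself); with p the personal best and l the best
informant, the center of gravity is g = x + c((p−x)+(l−x))/3 (or
g = x + c(p−x)/2 when the particle is its own best informant), and the
velocity update is v ← wv + (y − x) with y a random point of the ball
centered at g with radius ‖g−x‖.  y is drawn with uniform direction and
radius ~ U(0, ‖g−x‖): in 22 dimensions a volume-uniform draw concentrates
on the sphere surface, where a random direction is nearly orthogonal to
the useful one, and the swarm demonstrably stalls (the radial-uniform draw
recovers the expected geometric convergence on quadratics).  Informant
links are redrawn after any iteration that fails to improve the swarm
best.  Tuned defaults: S = 155, K = 89, w = 0.762, c = 1.037.

**DASA** discretizes per-parameter offsets into a layered graph with
vertices {0} ∪ {±b^k, k = ⌊log_b ε⌋ … ⌈log_b width⌉} (b = 10, ε = 1e−15,
so 35 vertices per layer and 22 layers).  Each layer carries a Cauchy
pheromone density with location l (initially 0) and scale s (initially 1);
a vertex's selection probability is the normalized density evaluated at
its offset value.  This concentrates mass on the zero and near-zero
offsets, so a typical ant path perturbs only a few parameters — and
all-zero paths become near-certain as s collapses, arming the restart
rule.  Each of m = 144 ants samples one offset per layer; candidates are
the clipped sums with the temporary best.  On improvement the temporary
best moves, each l jumps to the winning offset and s grows by
(1 + s⁺) = 1.575; otherwise s shrinks by (1 − s⁻) = 0.99 and l decays by
(1 − ρ) = 0.964.  After D² consecutive all-ants-all-zero iterations the
search restarts from a uniform random point with l = 0, s = 1; the global
best across restarts is returned.  The exact pheromone bookkeeping of the
original implementation is not published; this is a faithful variant of
the described behavior, not a bit-exact port.

**A717 stand-in**: restarts of a bound-constrained trust-region nonlinear
least-squares descent (scipy TRF, finite-difference Jacobians) from
uniform random points, each restart capped at 25 objective evaluations
(derivative evaluations included), 20 000 restarts at the full budget.
Its role is the derivative-based baseline: a capped local method restarted
at random performs poorly on this multi-modal landscape, which is the
qualitative behavior the comparison needs.  A restart whose residual
evaluation fails is abandoned with the failed evaluation charged at the
penalty value.

Convergence traces record (evaluation index, best objective) at every
improvement; the best-so-far step function is fully reconstructible from
them at any checkpoint, which keeps traces small without losing the
log-log convergence curves.

## Hyper-parameter tuning

Four hyper-parameters per meta-heuristic are sampled from an unscrambled
Gray-code Sobol' sequence (the all-zeros leading point is skipped;
configurable), mapped affinely to their ranges with integers rounded to
nearest and conditional caps applied using already-mapped coordinates
(K ≤ S−1 for PSO, s⁻ ≤ ρ for DASA).  Settings are scored by the median
final objective over independently seeded runs (median, not mean, because
run-to-run variance is heavy-tailed); ties break by mean, then sampling
order.  The study-scale campaign (2000 settings × 8 runs × 5e5
evaluations) is expressible but deliberately not run by the tests, which
exercise the harness at toy scale.

## Method comparison

Per-problem ensembles of seeded runs are summarized as
Best/Median/Worst/Average/Std of RMSE, boxplot statistics (linear-
interpolation quartiles, 1.5·IQR whiskers, notch half-width
1.57·IQR/√n), and averaged best-so-far curves at shared log-spaced
checkpoints.  Methods are compared across problems by Friedman-style
ranking — ranks 0…Nm−1 within each problem (mid-ranks on ties), averaged
over the Ntp problems — followed by the step-down Holm test against the
best-ranked method: z_i = |r0 − r_i| / sqrt(Nm(Nm+1)/(6 Ntp)), two-sided
normal p-values, thresholds α/i from the worst-ranked method down.
Integer global ranks cannot reproduce the printed fractional rank gaps;
per-problem rank averaging reproduces all six published z values to two
decimals and is therefore the implemented convention, with |z| reported.

The published full-scale median RMSE/RMSEm table (25 runs × 5e5
evaluations per cell — several CPU-months) is embedded as a constant in
`rabswitch.benchmark` and is the input to those z statistics; the package
recomputes the ranking and test statistics from it, and recomputes the
underlying ensembles only at reduced scale.

## Practical identifiability

Replicate noisy datasets are generated from the reference trajectory
(study condition: 20% noise), DE re-estimates the parameters on each, and
replicates producing an interquartile-fence outlier
(outside [Q1 − 1.5 IQR, Q3 + 1.5 IQR]) in *any* parameter are dropped.
The retained cloud yields per-parameter means, standard deviations, 95%
percentile confidence intervals (2.5th/97.5th percentiles by linear
interpolation; both bounds and length are reported), Freedman–Diaconis
histograms (h = 2 IQR/n^{1/3}; zero-IQR samples fall back to the sample
range), and a Pearson correlation matrix using the population-standard-
deviation convention.  Two-parameter objective slices (all other
coordinates at the reference) visualize the valleys behind the large
correlations — most prominently the c1/c5 production/turnover trade-off
of inactive Rab5 and the analogous c6/c16 pair for Rab7.

## Reduced problem sizes used by the test suite

The study-scale experiments (25 runs × 5e5 evaluations × 12 problems;
1000 Monte-Carlo replicates) are far beyond a single-machine test run, so
the suite asserts the study's qualitative findings at reduced scale, with
sizes chosen once, up front:

* Method comparison: noise-free CO data, budget 2·10⁴ evaluations,
  5 seeds per method — enough for the published ordering (DE best, the
  meta-heuristics well ahead of the restarted local solver) to be stable.
* DE output reconstruction: one run at budget 10⁵ reaches RMSE < 0.1 on
  noise-free CO data.
* Identifiability: 50 replicates at 20% noise under TO with a reduced
  per-replicate DE budget; the c1/c5 and c6/c16 couplings already
  dominate the correlation matrix at this scale, though their magnitudes
  remain below the near-unity values that full-budget fits produce —
  partially-converged fits still carry isotropic search scatter.

## Known limitations

* The A717 stand-in reproduces the role, not the internals, of the
  original adaptive nonlinear least-squares code; secant Hessian
  augmentation is not implemented.
* DASA's pheromone bookkeeping is a documented reconstruction from the
  published description.
* The noise convention behind the published noisy reference-point SSE
  values could not be reconciled with the stated noise model (their
  magnitudes are far below s²·ΣY²); those table rows are not used as
  checks.
* Fixed-seed bit-reproducibility holds on a given platform/library stack;
  floating-point reductions may differ across BLAS builds.
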