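"""The four bound-constrained minimizers against cheap analytic objectives."""

import numpy as np
import pytest

from rabswitch.objectives import PENALTY_VALUE, InfeasibleParameters
from rabswitch.optimizers import (DASAConfig, DEConfig, PSOConfig, SearchBounds,
                                  clip_to_bounds, dasa_build_graph, de_crossover,
                                  de_mutant, run_dasa, run_de, run_local_restarts,
                                  run_method, run_pso, _sample_hypersphere)

BOUNDS22 = SearchBounds(np.full(22, 1e-12),
                        np.concatenate([np.full(18, 4.0), np.full(4, 2.0)]))


def sphere(x):
    return float(np.sum((np.asarray(x) - 0.3) ** 2))


def sphere_residuals(x):
    return np.asarray(x) - 0.3


class TestBoundsAndClipping:
    def test_clip_to_closest_range_limit(self):
        b = SearchBounds(np.zeros(3), np.full(3, 4.0))
        np.testing.assert_array_equal(
            clip_to_bounds(np.array([4.7, 2.0, -1.0]), b), [4.0, 2.0, 0.0])

    def test_inside_point_unchanged(self, rng):
        b = SearchBounds(np.zeros(5), np.ones(5))
        x = rng.uniform(0.1, 0.9, 5)
        np.testing.assert_array_equal(clip_to_bounds(x, b), x)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchBounds(np.ones(3), np.ones(3))

    def test_default_bounds_match_search_space(self):
        b = SearchBounds.default()
        assert b.dim == 22
        assert np.all(b.upper[:18] == 4.0) and np.all(b.upper[18:] == 2.0)
        assert np.all(b.lower > 0.0)


class TestDEOperators:
    def test_zero_weight_rand1_mutant_is_a_parent(self, rng):
        pop = rng.uniform(size=(8, 5))
        m = de_mutant(pop, 2, 0, F=0.0, strategy=7, rng=rng)
        others = np.delete(pop, 2, axis=0)
        assert any(np.array_equal(m, row) for row in others)

    def test_rand_to_best_scheme_expands_correctly(self, rng):
        # strategy 8 with x_c = x_best: v = best + F (x1 - x2) for some pair
        pop = rng.uniform(size=(6, 4))
        best = 3
        m = de_mutant(pop, best, best, F=1.0, strategy=8, rng=rng)
        diffs = [pop[best] + (pop[i] - pop[j])
                 for i in range(6) for j in range(6) if i != j
                 and i != best and j != best]
        assert any(np.allclose(m, d) for d in diffs)

    def test_best_vector_may_replace_index(self, rng):
        pop = rng.uniform(size=(6, 4))
        live_best = rng.uniform(size=4)
        m = de_mutant(pop, 0, live_best, F=0.0, strategy=6, rng=rng)
        np.testing.assert_array_equal(m, live_best)  # best/1 with F=0

    def test_population_too_small_rejected(self, rng):
        pop = rng.uniform(size=(4, 3))
        with pytest.raises(ValueError):
            de_mutant(pop, 0, 1, F=0.5, strategy=10, rng=rng)  # rand/2 needs 5

    def test_full_crossover_returns_mutant(self, rng):
        cand, mut = rng.uniform(size=4), rng.uniform(size=4)
        np.testing.assert_array_equal(de_crossover(cand, mut, 1.0, "bin", rng), mut)

    def test_zero_crossover_changes_exactly_one_coordinate(self, rng):
        cand, mut = rng.uniform(size=10), rng.uniform(size=10)
        trial = de_crossover(cand, mut, 0.0, "bin", rng)
        assert int(np.sum(trial != cand)) == 1

    def test_exponential_crossover_block_is_contiguous_mod_d(self, rng):
        cand, mut = np.zeros(10), np.ones(10)
        trial = de_crossover(cand, mut, 0.8, "exp", rng)
        idx = np.flatnonzero(trial == 1.0)
        assert idx.size >= 1
        # a circularly contiguous block has at most one wrap gap
        gaps = np.diff(np.sort(idx))
        assert np.sum(gaps > 1) <= 1

    def test_against_brute_force_binomial_crossover_law(self):
        # same rng stream -> identical trial as a literal transcription
        cand, mut = np.zeros(6), np.ones(6)
        r1, r2 = np.random.default_rng(0), np.random.default_rng(0)
        trial = de_crossover(cand, mut, 0.4, "bin", r1)
        mask = r2.random(6) < 0.4
        mask[r2.integers(6)] = True
        np.testing.assert_array_equal(trial, np.where(mask, mut, cand))


class TestConvergenceOracles:
    def test_de_converges_on_shifted_sphere(self):
        res = run_de(sphere, BOUNDS22, DEConfig(), budget=50_000, seed=1)
        assert res.best_objective < 1e-5

    def test_pso_converges_on_shifted_sphere(self):
        res = run_pso(sphere, BOUNDS22, PSOConfig(), budget=100_000, seed=1)
        assert res.best_objective < 1e-4

    def test_dasa_converges_on_shifted_sphere(self):
        res = run_dasa(sphere, BOUNDS22, DASAConfig(), budget=100_000, seed=1)
        assert res.best_objective < 1e-2

    def test_local_solver_finds_interior_quadratic_optimum(self):
        res = run_local_restarts(sphere, sphere_residuals, BOUNDS22,
                                 n_restarts=1, evals_per_restart=200, seed=0)
        assert res.best_objective < 1e-6

    @pytest.mark.parametrize("method", ["de", "pso", "dasa", "a717"])
    def test_all_methods_solve_2d_quadratic(self, method):
        b = SearchBounds(np.zeros(2), np.ones(2))
        f = lambda x: float((x[0] - 0.4) ** 2 + (x[1] - 0.7) ** 2)
        res = run_method(method, f, b, budget=10_000, seed=2,
                         residuals_fn=lambda x: np.array([x[0] - 0.4, x[1] - 0.7]))
        assert res.best_objective < 1e-3


class TestRunContracts:
    @pytest.mark.parametrize("method", ["de", "pso", "dasa", "a717"])
    def test_bounds_trace_budget_and_determinism(self, method):
        kw = dict(residuals_fn=sphere_residuals)
        a = run_method(method, sphere, BOUNDS22, budget=3000, seed=9, **kw)
        b = run_method(method, sphere, BOUNDS22, budget=3000, seed=9, **kw)
        assert np.all(a.best_params >= BOUNDS22.lower)
        assert np.all(a.best_params <= BOUNDS22.upper)
        assert a.evaluations_used <= 3000
        assert np.all(np.diff(a.trace.best) < 0)           # improvements only
        assert np.all(np.diff(a.trace.evaluations) > 0)
        np.testing.assert_array_equal(a.best_params, b.best_params)
        assert a.best_objective == b.best_objective
        np.testing.assert_array_equal(a.trace.best, b.trace.best)

    def test_constant_objective(self):
        res = run_de(lambda x: 7.0, BOUNDS22, DEConfig(), budget=500, seed=0)
        assert res.best_objective == 7.0
        assert np.all(res.best_params <= BOUNDS22.upper)

    def test_trace_best_at_lookup(self):
        res = run_de(sphere, BOUNDS22, DEConfig(), budget=2000, seed=4)
        assert res.trace.best_at(2000) == res.best_objective
        assert res.trace.best_at(res.trace.evaluations[0]) == res.trace.best[0]

    def test_all_restarts_infeasible_yields_penalty(self):
        def bad_residuals(x):
            raise InfeasibleParameters
        res = run_local_restarts(sphere, bad_residuals, BOUNDS22,
                                 n_restarts=5, evals_per_restart=5, seed=1)
        assert res.best_objective == PENALTY_VALUE

    def test_local_restart_budget_accounting(self):
        res = run_local_restarts(sphere, sphere_residuals, BOUNDS22,
                                 n_restarts=4, evals_per_restart=25, seed=1)
        assert res.evaluations_used <= 100


class TestPSOGeometry:
    def test_degenerate_hypersphere_is_its_center(self, rng):
        center = rng.uniform(size=22)
        np.testing.assert_array_equal(
            _sample_hypersphere(rng, center, 0.0), center)

    def test_sample_lies_inside_the_ball(self, rng):
        center = np.zeros(22)
        for _ in range(50):
            y = _sample_hypersphere(rng, center, 2.0)
            assert np.linalg.norm(y) <= 2.0 + 1e-12

    def test_study_configuration_is_valid(self):
        cfg = PSOConfig(swarm=155, neighborhood=89, inertia=0.762,
                        acceleration=1.037)
        assert cfg.neighborhood <= cfg.swarm - 1

    def test_invalid_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            PSOConfig(swarm=10, neighborhood=10)


class TestDASAGraph:
    def test_vertex_count_for_study_geometry(self):
        b = SearchBounds(np.full(1, 1e-12), np.full(1, 4.0))
        cats = dasa_build_graph(b, base=10, precision=1e-15)
        # exponents -15..1 give 17 magnitudes per sign plus the zero vertex
        assert cats[0].size == 35
        assert 0.0 in cats[0]

    def test_one_layer_per_parameter(self):
        cats = dasa_build_graph(BOUNDS22, 10, 1e-15)
        assert len(cats) == 22

    def test_offsets_symmetric_and_sorted(self):
        cats = dasa_build_graph(BOUNDS22, 10, 1e-15)
        c = cats[0]
        assert np.all(np.diff(c) > 0)
        np.testing.assert_allclose(c, -c[::-1])

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            DASAConfig(scale_decrease=0.5, evaporation=0.1)  # s_minus > rho
        with pytest.raises(ValueError):
            DASAConfig(base=1)
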