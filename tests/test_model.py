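"""Kinetics, conservation identities and the integrator of the switch model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rabswitch.model import (NEGATIVITY_TOL, IntegrationFailure, ParameterVector,
                             StateTrajectory, TimeGrid, default_bounds,
                             default_time_grid, ode_rhs, reaction_rates,
                             reference_parameters, simulate)


def _random_inputs(data):
    state = np.array([data.draw(st.floats(0.0, 3.0)) for _ in range(4)])
    t = data.draw(st.floats(0.0, 2000.0))
    params = np.array([data.draw(st.floats(1e-6, 4.0)) for _ in range(18)]
                      + [data.draw(st.floats(1e-6, 2.0)) for _ in range(4)])
    return state, t, params


class TestReactionRates:
    def test_reference_values_of_constant_rates(self, ref_params):
        v = reaction_rates(np.array([0.5, 0.2, 0.7, 0.9]), 10.0, ref_params)
        assert v[0] == 1.0          # constant production of inactive Rab5
        assert v[3] == 0.483        # constant production of inactive Rab7

    def test_activation_rate_vanishes_at_time_zero(self, ref_params):
        v = reaction_rates(np.array([1.0, 0.5, 1.0, 0.5]), 0.0, ref_params)
        assert v[1] == 0.0

    def test_sigmoidal_activation_closed_form(self, ref_params):
        # v2 = c2 * r5 / (1 + exp((c3 - R5) c4)) * t/(100+t) evaluated by hand
        state = np.array([1.0, 0.001, 1.0, 0.001])
        v = reaction_rates(state, 100.0, ref_params)
        expected = 0.3 * 1.0 / (1.0 + np.exp((0.1 - 0.001) * 2.5)) * 0.5
        assert v[1] == pytest.approx(expected, rel=1e-12)

    def test_sigmoid_saturates_for_extreme_arguments(self):
        # huge gate steepness: the exponential must saturate, not overflow
        params = np.full(22, 4.0)
        params[18:] = 2.0
        v = reaction_rates(np.array([2.0, 0.0, 2.0, 0.0]), 10.0, params)
        assert np.all(np.isfinite(v))

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_rates_nonnegative_for_feasible_inputs(self, data):
        state, t, params = _random_inputs(data)
        v = reaction_rates(state, t, params)
        assert v.shape == (10,)
        assert np.all(v >= 0.0)


class TestOdeRhs:
    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_rab5_and_rab7_conservation_identities(self, data):
        # d(r5+R5)/dt = v1 - v3 and d(r7+R7)/dt = v4 - v8, exactly
        state, t, params = _random_inputs(data)
        v = reaction_rates(state, t, params)
        f = ode_rhs(state, t, params)
        assert f[0] + f[1] == pytest.approx(v[0] - v[2], abs=1e-12)
        assert f[2] + f[3] == pytest.approx(v[3] - v[7], abs=1e-12)

    def test_no_active_rab5_nulls_its_deactivation_paths(self, ref_params):
        state = np.array([1.0, 0.0, 1.0, 0.0])
        v = reaction_rates(state, 50.0, ref_params)
        f = ode_rhs(state, 50.0, ref_params)
        assert v[6] == 0.0 and v[8] == 0.0
        assert f[0] == pytest.approx(v[0] - v[1] - v[2], rel=1e-12)


class TestParameterVector:
    def test_reference_values_match_published_constants(self, ref_params):
        assert ref_params["c4"] == 2.5
        assert ref_params["c8"] == 3.0
        assert ref_params["c18"] == 0.15
        assert ref_params["R5_0"] == 0.001 and ref_params["R7_0"] == 0.001
        assert ref_params["r5_0"] == 1.0 and ref_params["r7_0"] == 1.0

    def test_reference_point_lies_inside_search_bounds(self, ref_params):
        lower, upper = default_bounds()
        assert np.all(ref_params.values > lower)
        assert np.all(ref_params.values < upper)
        assert ref_params.within_bounds()

    def test_dict_and_json_round_trip(self, ref_params, tmp_path):
        again = ParameterVector.from_dict(ref_params.to_dict())
        np.testing.assert_array_equal(again.values, ref_params.values)
        path = tmp_path / "params.json"
        ref_params.to_json(path)
        np.testing.assert_array_equal(
            ParameterVector.from_json(path).values, ref_params.values)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            ParameterVector(np.ones(21))


class TestTimeGrid:
    def test_default_grid_matches_data_description(self, default_grid):
        assert default_grid.n_points == 2781
        t = default_grid.times
        assert t[0] == 0.0 and t[-1] == 1551.0
        assert default_grid.spacing == pytest.approx(1551.0 / 2780.0, rel=1e-15)

    def test_degenerate_grids_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(0.0, 10.0, 1)
        with pytest.raises(ValueError):
            TimeGrid(10.0, 0.0, 5)


class TestSimulate:
    def test_switch_behavior_of_reference_trajectory(self, ref_traj):
        r5, R5, r7, R7 = (ref_traj.series(n) for n in ("r5", "R5", "r7", "R7"))
        # the mature state has more active Rab7 than active Rab5
        assert R7[-1] > R5[-1]
        # active Rab5 rises first: it crosses half its peak before Rab7 does
        t_half_R5 = ref_traj.times[np.argmax(R5 >= 0.5 * R5.max())]
        t_half_R7 = ref_traj.times[np.argmax(R7 >= 0.5 * R7.max())]
        assert t_half_R5 < t_half_R7
        # inactive pools stay near their initial level
        assert np.all(np.abs(r5 - 1.0) < 0.2) and np.all(np.abs(r7 - 1.0) < 0.2)

    def test_nonnegative_states_everywhere(self, ref_traj):
        assert np.all(ref_traj.states >= 0.0)

    def test_zero_length_interval_returns_initial_conditions(self, ref_params):
        traj = simulate(ref_params, TimeGrid(5.0, 5.0, 2))
        np.testing.assert_allclose(traj.states,
                                   np.tile(ref_params.initial_state, (2, 1)))

    def test_mean_square_of_inactive_pools_matches_reference_total(self, ref_traj):
        # cross-check against the noise-free totals-vs-actives SSE of 5549.839
        msq = np.mean(ref_traj.series("r5") ** 2 + ref_traj.series("r7") ** 2)
        assert msq == pytest.approx(5549.839 / 2781, rel=5e-3)

    def test_tolerance_halving_changes_solution_below_1e4(self, ref_params):
        a = simulate(ref_params, rel_tol=1e-8, abs_tol=1e-10)
        b = simulate(ref_params, rel_tol=5e-9, abs_tol=5e-11)
        rel = np.abs(a.states - b.states) / (1e-6 + np.abs(b.states))
        assert rel.max() < 1e-4

    def test_agrees_with_independent_lsoda_integration(self, ref_params, ref_traj):
        other = simulate(ref_params, method="lsoda", rel_tol=1e-10, abs_tol=1e-12)
        rel = np.abs(ref_traj.states - other.states) / (1e-6 + np.abs(other.states))
        assert rel.max() < 1e-4

    def test_finite_difference_consistency_at_interior_points(self, ref_params):
        grid = TimeGrid(0.0, 1551.0, 2781)
        traj = simulate(ref_params, grid)
        h = grid.spacing
        fd = (traj.states[2:] - traj.states[:-2]) / (2.0 * h)
        rhs = np.array([ode_rhs(traj.states[i], traj.times[i], ref_params)
                        for i in range(1, traj.times.size - 1)])
        assert np.max(np.abs(fd - rhs)) < 5e-3  # O(h^2) central difference

    def test_integration_failure_is_signalled(self):
        # negative kinetic constants leave the positivity-invariant regime
        # and blow up; the integrator must raise, not return garbage
        bad = np.full(22, -50.0)
        with pytest.raises((IntegrationFailure, Exception)):
            simulate(bad, TimeGrid(0.0, 1551.0, 100))

    def test_invalid_tolerances_rejected(self, ref_params):
        with pytest.raises(ValueError):
            simulate(ref_params, rel_tol=0.0)


class TestTrajectoryIO:
    def test_csv_round_trip(self, ref_params, tmp_path):
        traj = simulate(ref_params, TimeGrid(0.0, 50.0, 11))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        again = StateTrajectory.from_csv(path)
        np.testing.assert_allclose(again.states, traj.states, rtol=1e-12)
        np.testing.assert_allclose(again.times, traj.times, rtol=1e-12)
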