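"""Unit and property tests for the continuous Jellyfish Search Optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jsofs import (
    Candidate,
    JSOParams,
    SearchSpace,
    active_step,
    apply_boundary,
    init_swarm,
    ocean_current_step,
    optimize,
    passive_step,
    time_control,
)


def sphere(x):
    return float(np.sum(x * x))


# ---------------------------------------------------------------------------
# Elementary moves: hand-substituted values
# ---------------------------------------------------------------------------

class TestSteps:
    def test_ocean_current_zero_first_draw_is_identity(self):
        x = np.array([1.0, -2.0])
        out = ocean_current_step(x, np.array([5.0, 5.0]), np.array([1.0, 1.0]),
                                 beta=3.0, draws=(0.0, 0.7))
        np.testing.assert_array_equal(out, x)

    def test_ocean_current_hand_value(self):
        # x=0, best=1, mean=1, beta=3, r1=r2=1 -> 0 + 1*(1 - 3*1*1) = -2
        out = ocean_current_step(np.array([0.0]), np.array([1.0]),
                                 np.array([1.0]), beta=3.0, draws=(1.0, 1.0))
        np.testing.assert_allclose(out, [-2.0])

    def test_ocean_current_zero_mean_reduces_to_best_attraction(self):
        x, best = np.array([2.0, -1.0]), np.array([0.5, 0.5])
        out = ocean_current_step(x, best, np.zeros(2), beta=3.0, draws=(1.0, 0.3))
        np.testing.assert_allclose(out, x + best)

    @pytest.mark.parametrize(
        "x, lo, hi, gamma, r, expected",
        [
            ([0.0], [-1.0], [1.0], 0.1, 0.5, [0.1]),
            ([3.0], [0.0], [10.0], 0.0001, 0.0, [3.0]),     # zero draw
            ([2.0], [2.0], [2.0], 0.1, 0.9, [2.0]),         # degenerate box
        ],
    )
    def test_passive_step_values(self, x, lo, hi, gamma, r, expected):
        space = SearchSpace(np.array(lo), np.array(hi))
        out = passive_step(np.array(x), space, gamma, r)
        np.testing.assert_allclose(out, expected)

    def test_active_step_toward_better_partner(self):
        out = active_step(np.array([0.0]), 5.0, np.array([2.0]), 1.0, 0.5)
        np.testing.assert_allclose(out, [1.0])

    def test_active_step_away_from_worse_partner(self):
        out = active_step(np.array([0.0]), 1.0, np.array([2.0]), 5.0, 0.5)
        np.testing.assert_allclose(out, [-1.0])

    def test_active_step_zero_draw_is_identity(self):
        xi = np.array([3.0, 4.0])
        out = active_step(xi, 1.0, np.array([0.0, 0.0]), 2.0, 0.0)
        np.testing.assert_array_equal(out, xi)


class TestTimeControl:
    @pytest.mark.parametrize("draw", [0.0, 0.25, 0.5, 1.0])
    def test_vanishes_at_final_iteration(self, draw):
        assert time_control(100, 100, draw) == 0.0

    def test_hand_values(self):
        assert time_control(0, 100, 1.0) == 1.0
        assert time_control(0, 100, 0.5) == 0.0

    def test_abs_mode(self):
        assert time_control(0, 100, 0.0) == -1.0
        assert time_control(0, 100, 0.0, abs_mode=True) == 1.0

    def test_zero_max_iter_rejected(self):
        with pytest.raises(ValueError):
            time_control(0, 0, 0.5)

    @given(t=st.integers(0, 500), draw=st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_envelope_bound(self, t, draw):
        ct = time_control(t, 500, draw)
        assert abs(ct) <= 1.0 - t / 500 + 1e-12


class TestBoundary:
    @pytest.mark.parametrize("mode", ["clip", "reflect", "wrap"])
    def test_interior_point_unchanged(self, mode):
        space = SearchSpace(np.array([0.0, -1.0]), np.array([1.0, 1.0]))
        x = np.array([0.5, 0.25])
        np.testing.assert_array_equal(apply_boundary(x, space, mode), x)

    @pytest.mark.parametrize(
        "mode, x, expected",
        [("clip", 1.5, 1.0), ("wrap", 1.5, 0.5), ("reflect", 1.5, 0.5),
         ("clip", -0.3, 0.0), ("wrap", -0.3, 0.7), ("reflect", -0.3, 0.3)],
    )
    def test_unit_box_repairs(self, mode, x, expected):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        out = apply_boundary(np.array([x]), space, mode)
        np.testing.assert_allclose(out, [expected])

    def test_unknown_mode_rejected(self):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="unknown boundary mode"):
            apply_boundary(np.array([0.5]), space, "bounce")

    @given(
        x=st.floats(-100, 100),
        mode=st.sampled_from(["clip", "reflect", "wrap"]),
    )
    @settings(derandomize=True, max_examples=100)
    def test_always_feasible(self, x, mode):
        space = SearchSpace(np.array([-2.0]), np.array([3.0]))
        out = apply_boundary(np.array([x]), space, mode)
        assert -2.0 <= out[0] <= 3.0


# ---------------------------------------------------------------------------
# Population machinery
# ---------------------------------------------------------------------------

class TestInitSwarm:
    def test_degenerate_box_collapses_to_point(self):
        space = SearchSpace(np.array([0.0]), np.array([0.0]))
        swarm = init_swarm(space, JSOParams(pop_size=5, seed=1), sphere)
        for m in swarm.members:
            np.testing.assert_array_equal(m.position, [0.0])

    def test_best_is_minimum_of_initial_costs(self):
        space = SearchSpace(-np.ones(3), np.ones(3))
        swarm = init_swarm(space, JSOParams(pop_size=5, seed=2), sphere)
        assert swarm.best.cost == min(m.cost for m in swarm.members)

    def test_same_seed_identical_swarms(self):
        space = SearchSpace(-np.ones(4), np.ones(4))
        params = JSOParams(pop_size=6, seed=9)
        a = init_swarm(space, params, sphere)
        b = init_swarm(space, params, sphere)
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.position, mb.position)

    def test_chaotic_mode_stays_in_box_and_is_seeded(self):
        space = SearchSpace(np.array([-3.0, 0.0]), np.array([1.0, 2.0]))
        params = JSOParams(pop_size=10, seed=4, init_mode="chaotic")
        a = init_swarm(space, params, sphere)
        b = init_swarm(space, params, sphere)
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.position, mb.position)
            assert np.all(ma.position >= space.lower)
            assert np.all(ma.position <= space.upper)

    def test_non_finite_objective_is_diagnosed(self):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="non-finite"):
            init_swarm(space, JSOParams(pop_size=3, seed=0),
                       lambda x: float("inf"))

    def test_seed_positions_are_injected(self):
        space = SearchSpace(-np.ones(3), np.ones(3))
        swarm = init_swarm(space, JSOParams(pop_size=4, seed=0), sphere,
                           seed_positions=[np.zeros(3)])
        np.testing.assert_array_equal(swarm.members[0].position, np.zeros(3))
        assert swarm.best.cost == 0.0


class TestOptimize:
    def test_constant_objective_flat_trace(self):
        space = SearchSpace(-np.ones(2), np.ones(2))
        best, trace = optimize(lambda x: 0.0, space,
                               JSOParams(pop_size=4, max_iter=10, seed=0))
        assert best.cost == 0.0
        assert all(r.best_cost == 0.0 for r in trace)
        assert len(trace) == 10

    def test_trace_best_cost_non_increasing(self):
        space = SearchSpace(-5 * np.ones(4), 5 * np.ones(4))
        _, trace = optimize(sphere, space,
                            JSOParams(pop_size=10, max_iter=60, seed=3))
        costs = [r.best_cost for r in trace]
        assert all(a >= b for a, b in zip(costs, costs[1:]))

    def test_same_seed_bit_identical_trace_and_best(self):
        space = SearchSpace(-5 * np.ones(3), 5 * np.ones(3))
        params = JSOParams(pop_size=8, max_iter=40, seed=17)
        b1, t1 = optimize(sphere, space, params)
        b2, t2 = optimize(sphere, space, params)
        assert b1.cost == b2.cost
        np.testing.assert_array_equal(b1.position, b2.position)
        assert [(r.best_cost, r.mean_cost) for r in t1] == \
               [(r.best_cost, r.mean_cost) for r in t2]

    def test_every_evaluated_position_is_feasible(self):
        space = SearchSpace(-2 * np.ones(3), 2 * np.ones(3))

        def checked(x):
            assert np.all(x >= space.lower - 1e-12)
            assert np.all(x <= space.upper + 1e-12)
            return sphere(x)

        optimize(checked, space, JSOParams(pop_size=6, max_iter=30, seed=5))

    @pytest.mark.parametrize("replacement", ["greedy", "always"])
    def test_runs_under_both_replacement_rules(self, replacement):
        space = SearchSpace(-5 * np.ones(3), 5 * np.ones(3))
        best, trace = optimize(
            sphere, space,
            JSOParams(pop_size=8, max_iter=30, seed=1, replacement=replacement),
        )
        costs = [r.best_cost for r in trace]
        assert all(a >= b for a, b in zip(costs, costs[1:]))
        assert best.cost <= costs[0]

    def test_converges_on_small_sphere(self):
        space = SearchSpace(-10 * np.ones(5), 10 * np.ones(5))
        best, _ = optimize(sphere, space,
                           JSOParams(pop_size=20, max_iter=200, seed=0))
        assert best.cost < 1e-4

    def test_shifted_quadratic_target_found(self):
        target = np.array([1.5, -2.0, 0.5])
        space = SearchSpace(-5 * np.ones(3), 5 * np.ones(3))
        best, _ = optimize(lambda x: float(np.sum((x - target) ** 2)), space,
                           JSOParams(pop_size=20, max_iter=200, seed=2))
        np.testing.assert_allclose(best.position, target, atol=0.01)

    def test_non_finite_cost_mid_run_reports_iteration(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            return float("nan") if calls["n"] > 10 else sphere(x)

        space = SearchSpace(-np.ones(2), np.ones(2))
        with pytest.raises(ValueError, match="iteration"):
            optimize(flaky, space, JSOParams(pop_size=5, max_iter=10, seed=0))


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(pop_size=1), dict(beta=0.0), dict(gamma=-0.1),
         dict(switch_threshold=1.5), dict(boundary_mode="x"),
         dict(replacement="sometimes"), dict(max_iter=0)],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            JSOParams(**kw)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([1.0]), np.array([0.0]))
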