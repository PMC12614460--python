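"""Salp swarm mechanics: schedule, leader/follower updates, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from salp_clinrisk import ssa
from salp_clinrisk.ssa import (
    Dimension,
    SearchSpace,
    compute_c1,
    decode_position,
    optimize,
    update_followers,
    update_leader,
)
from salp_clinrisk.tuning import rf_search_space, xgb_search_space


class FakeUniform:
    """Stands in for a Generator, replaying scripted uniform draws."""

    def __init__(self, *draws):
        self.draws = list(draws)

    def uniform(self, size=None):
        out = self.draws.pop(0)
        return np.full(size, out) if size is not None else out


BOX_1D = SearchSpace([Dimension("x", 0.0, 10.0)])


class TestC1Schedule:
    def test_starts_at_two(self):
        assert compute_c1(0, 50) == 2.0
        assert compute_c1(0, 1) == 2.0

    def test_midpoint_and_endpoint_values(self):
        assert compute_c1(25, 50) == pytest.approx(2 * np.exp(-4), rel=1e-12)
        assert compute_c1(50, 50) == pytest.approx(2 * np.exp(-16), rel=1e-12)
        assert compute_c1(50, 50) == pytest.approx(2.2507e-7, rel=1e-4)

    def test_rejects_nonpositive_horizon(self):
        with pytest.raises(ValueError):
            compute_c1(0, 0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(horizon=st.integers(1, 1000))
    def test_strictly_decreasing_over_iterations(self, horizon):
        values = [compute_c1(t, horizon) for t in range(horizon + 1)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestLeaderUpdate:
    def test_zero_c1_collapses_to_food_source(self):
        rng = np.random.default_rng(0)
        food = np.array([5.0])
        for _ in range(10):
            assert update_leader(food, BOX_1D, 0.0, rng)[0] == 5.0

    def test_additive_branch_hand_value(self):
        # c3 = 0.2 (< 0.5), c2 = 0.5, c1 = 0.5: 5 + 0.5*(10*0.5 + 0) = 7.5
        rng = FakeUniform(0.5, 0.2)
        out = update_leader(np.array([5.0]), BOX_1D, 0.5, rng)
        assert out[0] == pytest.approx(7.5)

    def test_subtractive_branch_clamps_at_lower_bound(self):
        # c3 = 0.7, c2 = 1, c1 = 1: raw 5 - 10 = -5, clamped to 0
        rng = FakeUniform(1.0, 0.7)
        out = update_leader(np.array([5.0]), BOX_1D, 1.0, rng)
        assert out[0] == 0.0


class TestFollowerUpdate:
    def test_equal_positions_are_fixed_point(self):
        pos = np.full((4, 3), 2.5)
        assert np.array_equal(update_followers(pos), pos)

    def test_pairwise_midpoint(self):
        out = update_followers(np.array([[0.0], [2.0]]))
        assert out.tolist() == [[0.0], [1.0]]

    def test_sequential_sweep_uses_updated_neighbor(self):
        out = update_followers(np.array([[0.0], [2.0], [4.0]]))
        assert out.tolist() == [[0.0], [1.0], [2.5]]

    def test_rejects_single_salp(self):
        with pytest.raises(ValueError):
            update_followers(np.array([[1.0]]))


class TestDecodePosition:
    def test_rf_lower_bounds(self):
        space = rf_search_space()
        assert decode_position(space.lower, space) == {
            "n_estimators": 50,
            "max_depth": 3,
            "min_samples_split": 2,
            "min_samples_leaf": 1,
        }

    def test_xgb_lower_bounds(self):
        space = xgb_search_space()
        assert decode_position(space.lower, space) == {
            "n_estimators": 50,
            "max_depth": 3,
            "learning_rate": 0.01,
            "gamma": 0.0,
            "min_child_weight": 1,
        }

    def test_integer_rounding_half_away_from_zero(self):
        space = rf_search_space()
        decoded = decode_position(np.array([250.6, 10.5, 2.2, 1.0]), space)
        assert decoded["n_estimators"] == 251
        assert decoded["max_depth"] == 11

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            decode_position(np.array([1.0, 2.0]), BOX_1D)


class TestOptimize:
    SPHERE_SPACE = SearchSpace([Dimension("a", -5, 5), Dimension("b", -5, 5)])

    @staticmethod
    def sphere(x):
        return float(x @ x)

    def test_sphere_convergence_across_seeds(self):
        for seed in range(10):
            res = optimize(self.sphere, self.SPHERE_SPACE, n_salps=20,
                           n_iterations=100, seed=seed)
            assert res.best_fitness < 1e-3, (seed, res.best_fitness)

    def test_v_function_locates_minimum(self):
        res = optimize(lambda x: abs(float(x[0]) - 3.0), BOX_1D,
                       n_salps=10, n_iterations=50, seed=0)
        assert abs(res.best_assignment["x"] - 3.0) < 0.1

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_trace_non_increasing_on_noise_fitness(self, seed):
        rng = np.random.default_rng(seed)
        res = optimize(lambda x: float(rng.uniform()), BOX_1D,
                       n_salps=4, n_iterations=20, seed=seed)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.trace[-1] == res.best_fitness

    def test_elitism_best_equals_min_of_evaluated(self):
        evaluated = []

        def recording(x):
            v = self.sphere(x)
            evaluated.append(v)
            return v

        res = optimize(recording, self.SPHERE_SPACE, n_salps=8, n_iterations=30, seed=3)
        assert res.best_fitness == min(evaluated)
        assert res.n_evaluations == len(evaluated) == 8 * 30

    def test_positions_stay_in_box(self):
        seen = []

        def recording(x):
            seen.append(x.copy())
            return self.sphere(x)

        optimize(recording, self.SPHERE_SPACE, n_salps=6, n_iterations=25, seed=5)
        arr = np.array(seen)
        assert np.all(arr >= -5.0) and np.all(arr <= 5.0)

    def test_exploration_precedes_exploitation(self):
        """Leader steps shrink: early mean step exceeds late mean step."""
        wins = 0
        for seed in range(10):
            res = optimize(self.sphere, self.SPHERE_SPACE, n_salps=10,
                           n_iterations=60, seed=seed)
            early = res.leader_steps[:15].mean()
            late = res.leader_steps[-15:].mean()
            wins += early > late
        assert wins >= 9

    def test_leader_start_pins_first_evaluation(self):
        first = {}

        def recording(x):
            first.setdefault("pos", x.copy())
            return self.sphere(x)

        optimize(recording, self.SPHERE_SPACE, n_salps=5, n_iterations=2,
                 seed=0, x0=np.array([1.0, -1.0]))
        assert np.array_equal(first["pos"], [1.0, -1.0])

    def test_fitness_error_carries_context(self):
        def broken(x):
            raise RuntimeError("boom")

        with pytest.raises(ssa.FitnessEvaluationError, match="iteration 1, salp 0"):
            optimize(broken, BOX_1D, n_salps=3, n_iterations=2, seed=0)

    def test_simultaneous_follower_variant_also_converges(self):
        res = optimize(self.sphere, self.SPHERE_SPACE, n_salps=20,
                       n_iterations=100, seed=1, sequential_followers=False)
        assert res.best_fitness < 1e-2

    def test_rejects_degenerate_budgets(self):
        with pytest.raises(ValueError):
            optimize(self.sphere, self.SPHERE_SPACE, n_salps=1, n_iterations=5)
        with pytest.raises(ValueError):
            optimize(self.sphere, self.SPHERE_SPACE, n_salps=3, n_iterations=0)


class TestSearchSpaceInvariants:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError, match="lower < upper"):
            Dimension("bad", 5.0, 5.0)

    def test_uniform_sampling_within_bounds(self):
        space = xgb_search_space()
        pts = space.sample_uniform(500, np.random.default_rng(0))
        assert np.all(pts >= space.lower) and np.all(pts <= space.upper)
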