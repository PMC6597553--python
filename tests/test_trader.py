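"""Unit and property tests for the Trader optimizer core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trader_dti.benchmarks import get_benchmark
from trader_dti.trader import (
    CandidateSolution,
    ObjectiveFunction,
    TraderConfig,
    allocate_groups,
    greedy_accept,
    init_population,
    master_exchange,
    master_slave_distribute,
    run,
    slave_self_change,
    update_properties,
)


def sphere_objective(n, bounds=(-100.0, 100.0)):
    return ObjectiveFunction(lambda x: float(np.sum(x * x)), n, bounds)


class TestInitPopulation:
    def test_bounds_containment_and_equal_properties(self):
        cfg = TraderConfig(10, 2, 5, bounds=(-1.0, 1.0), seed=7)
        state = init_population(cfg, sphere_objective(3, (-1, 1)))
        assert state.X.shape == (10, 3)
        assert np.all(state.X >= -1) and np.all(state.X <= 1)
        assert np.array_equal(state.properties, np.ones(2))

    def test_best_is_population_minimum(self):
        cfg = TraderConfig(12, 3, 5, bounds=(-5.0, 5.0), seed=3)
        state = init_population(cfg, sphere_objective(4, (-5, 5)))
        assert state.best_f == pytest.approx(state.f.min())
        assert state.best.objective_value == state.best_f

    def test_same_seed_identical_population(self):
        cfg = TraderConfig(10, 2, 5, bounds=(-1.0, 1.0), seed=7)
        a = init_population(cfg, sphere_objective(3, (-1, 1)))
        b = init_population(cfg, sphere_objective(3, (-1, 1)))
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.f, b.f)

    def test_nonfinite_objective_aborts_with_point(self):
        bad = ObjectiveFunction(lambda x: float("inf"), 2, (-1, 1))
        cfg = TraderConfig(6, 2, 5, bounds=(-1.0, 1.0), seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            init_population(cfg, bad)

    def test_population_smaller_than_2T_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            TraderConfig(5, 3, 5).validate()


class TestAllocateGroups:
    def _state(self, C, T, properties, seed=0):
        cfg = TraderConfig(C, T, 1, bounds=(-1.0, 1.0), seed=seed)
        state = init_population(cfg, sphere_objective(2, (-1, 1)))
        state.properties = np.asarray(properties, dtype=float)
        return state, cfg

    def test_equal_shares(self):
        state, cfg = self._state(20, 4, [1, 1, 1, 1])
        allocate_groups(state, cfg)
        assert np.array_equal(state.group_sizes, [5, 5, 5, 5])

    def test_proportional_shares_hand_computed(self):
        # 2 + round(0.25*4) = 3 twice, 2 + round(0.5*4) = 4
        state, cfg = self._state(10, 3, [1, 1, 2])
        allocate_groups(state, cfg)
        assert np.array_equal(state.group_sizes, [3, 3, 4])

    def test_membership_is_exhaustive_and_consistent(self):
        state, cfg = self._state(15, 3, [3.0, 1.0, 2.0])
        allocate_groups(state, cfg)
        assert np.all(state.groups >= 0)
        for g, members in enumerate(state.members):
            assert len(members) == state.group_sizes[g]
            assert np.all(state.groups[members] == g)

    def test_richest_trader_claims_best_solution(self):
        state, cfg = self._state(12, 3, [1.0, 5.0, 2.0])
        allocate_groups(state, cfg)
        assert state.groups[np.argmin(state.f)] == 1

    def test_nonpositive_property_rejected(self):
        state, cfg = self._state(10, 2, [1.0, 0.0])
        with pytest.raises(ValueError, match="strictly positive"):
            allocate_groups(state, cfg)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        T=st.integers(1, 8),
        extra=st.integers(0, 60),
        pseed=st.integers(0, 2**31 - 1),
    )
    def test_property_conservation_and_min_size(self, T, extra, pseed):
        """Allocation always conserves the population and never starves a
        group below two members, for arbitrary positive property vectors."""
        C = 2 * T + extra
        prng = np.random.default_rng(pseed)
        state, cfg = self._state(C, T, prng.uniform(0.01, 100.0, T), seed=pseed % 1000)
        allocate_groups(state, cfg)
        assert state.group_sizes.sum() == C
        assert state.group_sizes.min() >= 2

    def test_proportionality_with_large_remainder(self):
        state, cfg = self._state(120, 2, [7.0, 1.0])
        allocate_groups(state, cfg)
        assert state.group_sizes[0] > state.group_sizes[1]


class TestGreedyAccept:
    obj = sphere_objective(2, (-10, 10))

    def test_strict_improvement_accepted(self):
        inc = CandidateSolution(np.array([2.0, 1.0]), None, 5.0)
        out = greedy_accept(np.array([2.0, 0.9]), inc, self.obj)
        assert out is not inc
        assert out.objective_value == pytest.approx(4.81)

    def test_tie_rejected(self):
        inc = CandidateSolution(np.array([1.0, 2.0]), None, 5.0)
        out = greedy_accept(np.array([2.0, 1.0]), inc, self.obj)
        assert out is inc

    def test_nonfinite_trial_rejected(self):
        bad = ObjectiveFunction(lambda x: float("nan"), 2, (-10, 10))
        inc = CandidateSolution(np.array([1.0, 1.0]), None, 2.0)
        assert greedy_accept(np.array([0.0, 0.0]), inc, bad) is inc

    def test_objective_sequence_non_increasing(self, rng):
        inc = CandidateSolution(np.array([5.0, 5.0]), None, 50.0)
        values = [inc.objective_value]
        for _ in range(1000):
            inc = greedy_accept(rng.uniform(-10, 10, 2), inc, self.obj)
            values.append(inc.objective_value)
        assert np.all(np.diff(values) <= 0)


class TestOperators:
    def _allocated_state(self, C=12, T=2, n=4, seed=5):
        cfg = TraderConfig(C, T, 10, bounds=(-10.0, 10.0), seed=seed)
        obj = sphere_objective(n, (-10, 10))
        state = init_population(cfg, obj)
        allocate_groups(state, cfg)
        return state, cfg, obj

    def test_master_slave_identical_members_fixed_point(self):
        state, cfg, obj = self._allocated_state(C=4, T=2)
        g = 0
        members = state.members[g]
        state.X[members] = state.X[members[0]]
        state.f[members] = obj(state.X[members[0]])
        before = state.X[members].copy()
        master_slave_distribute(state, g, obj, np.random.default_rng(0))
        assert np.array_equal(state.X[members], before)

    def test_master_slave_group_objective_never_increases(self):
        state, cfg, obj = self._allocated_state(C=20, T=2, n=6)
        total = state.f.sum()
        rng = np.random.default_rng(1)
        for _ in range(100):
            for g in range(2):
                master_slave_distribute(state, g, obj, rng)
            new_total = state.f.sum()
            assert new_total <= total + 1e-12
            total = new_total

    def test_master_unchanged_by_distribution(self):
        state, cfg, obj = self._allocated_state()
        g = 0
        m = state.members[g][np.argmin(state.f[state.members[g]])]
        before = state.X[m].copy()
        master_slave_distribute(state, g, obj, np.random.default_rng(2))
        assert np.array_equal(state.X[m], before)

    def test_self_change_zero_vector_fixed_point(self):
        state, cfg, obj = self._allocated_state(C=6, T=2, n=3)
        g = 0
        members = state.members[g]
        master = members[np.argmin(state.f[members])]
        slave = [j for j in members if j != master][0]
        state.X[slave] = 0.0
        state.f[slave] = 0.0
        slave_self_change(state, g, obj, cfg, np.random.default_rng(3))
        assert np.array_equal(state.X[slave], np.zeros(3))

    def test_self_change_respects_bounds(self):
        state, cfg, obj = self._allocated_state(C=10, T=2, n=5)
        rng = np.random.default_rng(4)
        for _ in range(50):
            for g in range(2):
                slave_self_change(state, g, obj, cfg, rng)
        assert np.all(state.X >= -10) and np.all(state.X <= 10)

    def test_self_change_alone_improves_sphere(self):
        """Repeated multiplicative self-perturbation shrinks a convex
        objective from a random start in nearly every seeded run."""
        wins = 0
        obj = sphere_objective(10, (-100, 100))
        for seed in range(50):
            cfg = TraderConfig(6, 2, 1, bounds=(-100.0, 100.0), seed=seed)
            state = init_population(cfg, obj)
            allocate_groups(state, cfg)
            start = state.f.min()
            rng = np.random.default_rng(seed + 1000)
            for _ in range(500):
                for g in range(2):
                    slave_self_change(state, g, obj, cfg, rng)
            wins += state.f.min() < start
        assert wins >= 49

    def test_master_exchange_single_trader_noop(self):
        cfg = TraderConfig(6, 1, 1, bounds=(-10.0, 10.0), seed=0)
        obj = sphere_objective(3, (-10, 10))
        state = init_population(cfg, obj)
        allocate_groups(state, cfg)
        before = state.X.copy()
        master_exchange(state, obj, np.random.default_rng(0))
        assert np.array_equal(state.X, before)

    def test_master_exchange_identical_masters_fixed_point(self):
        state, cfg, obj = self._allocated_state(C=4, T=2, n=3)
        state.X[:] = state.X[0]
        state.f[:] = obj(state.X[0])
        before = state.X.copy()
        master_exchange(state, obj, np.random.default_rng(5))
        assert np.array_equal(state.X, before)

    def test_master_exchange_full_import_of_optimum(self):
        """With one variable the single positional copy is a full import, so
        an optimal master propagates to the other group's master."""
        cfg = TraderConfig(4, 2, 1, bounds=(-10.0, 10.0), seed=1)
        obj = sphere_objective(1, (-10, 10))
        state = init_population(cfg, obj)
        allocate_groups(state, cfg)
        m0 = state.members[0][np.argmin(state.f[state.members[0]])]
        state.X[m0] = 0.0
        state.f[m0] = 0.0
        master_exchange(state, obj, np.random.default_rng(0))
        m1 = state.members[1][np.argmin(state.f[state.members[1]])]
        assert state.f[m1] == 0.0


class TestUpdateProperties:
    def _state_with_f(self, f_values, T, members):
        cfg = TraderConfig(len(f_values), T, 1, bounds=(-1.0, 1.0), seed=0)
        state = init_population(cfg, sphere_objective(2, (-1, 1)))
        state.f = np.asarray(f_values, dtype=float)
        state.members = [np.asarray(m) for m in members]
        return state, cfg

    def test_inverse_fitness_perfect_members(self):
        state, cfg = self._state_with_f([0.0, 0.0], 1, [[0, 1]])
        update_properties(state, cfg)
        assert state.properties[0] == pytest.approx(2.0)

    def test_literal_sum_is_raw_sum(self):
        state, cfg = self._state_with_f([1.0, 3.0], 1, [[0, 1]])
        cfg = TraderConfig(2, 1, 1, bounds=(-1.0, 1.0), property_mode="literal_sum")
        update_properties(state, cfg)
        assert state.properties[0] == pytest.approx(4.0)

    def test_inverse_fitness_rewards_improvement(self):
        state, cfg = self._state_with_f([1.0, 2.0, 3.0, 4.0], 2, [[0, 1], [2, 3]])
        update_properties(state, cfg)
        before = state.properties[0]
        state.f[0] = 0.5
        update_properties(state, cfg)
        assert state.properties[0] > before

    def test_negative_objectives_keep_properties_positive(self):
        for mode in ("inverse_fitness", "literal_sum"):
            state, _ = self._state_with_f([-1.5, 0.2, -0.1, 3.0], 2, [[0, 1], [2, 3]])
            cfg = TraderConfig(4, 2, 1, bounds=(-1.0, 1.0), property_mode=mode)
            update_properties(state, cfg)
            assert np.all(state.properties > 0)


class TestRun:
    def test_zero_iterations_degenerate(self):
        obj = sphere_objective(3, (-1, 1))
        cfg = TraderConfig(10, 2, 0, bounds=(-1.0, 1.0), seed=9)
        best, history = run(cfg, obj)
        init = init_population(cfg, obj, np.random.default_rng(9))
        assert history.size == 0
        assert best.objective_value == pytest.approx(init.best_f)

    def test_history_non_increasing(self, quick_config):
        _, history = run(quick_config, sphere_objective(5))
        assert np.all(np.diff(history) <= 0)

    def test_bitwise_reproducibility(self, quick_config):
        b1, h1 = run(quick_config, sphere_objective(5))
        b2, h2 = run(quick_config, sphere_objective(5))
        assert np.array_equal(b1.variables, b2.variables)
        assert np.array_equal(h1, h2)

    def test_improves_over_initial_population(self):
        obj = sphere_objective(10)
        cfg = TraderConfig(30, 3, 100, bounds=(-100.0, 100.0), seed=11)
        init_best = init_population(cfg, obj, np.random.default_rng(11)).best_f
        best, _ = run(cfg, obj)
        assert best.objective_value < init_best

    def test_literal_sum_mode_still_optimizes(self):
        cfg = TraderConfig(
            30, 3, 100, bounds=(-100.0, 100.0), seed=2, property_mode="literal_sum"
        )
        best, history = run(cfg, sphere_objective(5))
        assert np.all(np.diff(history) <= 0)
        assert best.objective_value < history[0] + 1e-12
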