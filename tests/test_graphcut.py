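import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uscut.graphcut import (
    CostProfile,
    brute_force_min_cut,
    build_graph,
    compute_costs,
    compute_terminal_weights,
    solve_min_cut,
)
from uscut.template import RaySamples, build_template

from conftest import random_profile

# the two worked rays: gray values sampled toward a brighter and a darker
# surrounding, seed-region average 100
BRIGHT_GRAY = np.array([109.0, 110.0, 94.0, 155.0, 160.0, 131.0])
DARK_GRAY = np.array([95.0, 101.0, 98.0, 55.0, 40.0, 60.0])


def _samples(gray_rows, seed_avg=100.0):
    t = build_template((50, 50), radius=12, R=len(gray_rows), L=len(gray_rows[0]))
    return RaySamples(template=t, gray=np.array(gray_rows, float), seed_avg=seed_avg)


class TestCosts:
    def test_absolute_difference_to_seed_average(self):
        p = compute_costs(_samples([BRIGHT_GRAY, DARK_GRAY, BRIGHT_GRAY]))
        np.testing.assert_allclose(p.costs[0], [9, 10, 6, 55, 60, 31])
        np.testing.assert_allclose(p.costs[1], [5, 1, 2, 45, 60, 40])

    def test_cost_zero_at_seed_level(self):
        p = compute_costs(_samples([[100.0, 100.0, 100.0]] * 3))
        assert (p.costs == 0).all()


class TestTerminalWeights:
    def test_worked_bright_ray(self):
        w = compute_terminal_weights(np.array([9.0, 10, 6, 55, 60, 31]))
        np.testing.assert_allclose(w, [-9, 1, -4, 49, 5, 31])

    def test_worked_dark_ray(self):
        w = compute_terminal_weights(np.array([5.0, 1, 2, 45, 60, 40]))
        np.testing.assert_allclose(w, [-5, -4, 1, 43, 15, 40])

    def test_constant_costs(self):
        w = compute_terminal_weights(np.array([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(w, [-5, 0, 5])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_terminal_weights(np.array([3.0]))

    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            compute_terminal_weights(np.array([1.0, -2.0, 3.0]))


class TestBuildGraph:
    def test_edge_counts_small_template(self):
        p = random_profile(np.random.default_rng(1), R=4, L=3)
        g = build_graph(p, delta_r=1)
        nodes = [n for n in g.graph if n not in ("s", "t")]
        assert len(nodes) == 12
        inf = g.inf_capacity
        intra = [
            (u, v) for u, v, c in g.graph.edges(data="capacity")
            if c == inf and u[0] == v[0]
        ]
        inter = [
            (u, v) for u, v, c in g.graph.edges(data="capacity")
            if c == inf and u[0] != v[0]
        ]
        assert len(intra) == 4 * (3 - 1)
        assert len(inter) == 2 * 4 * 3

    def test_inf_exceeds_total_terminal_capacity(self):
        p = random_profile(np.random.default_rng(2), R=5, L=4)
        g = build_graph(p, delta_r=2)
        total = sum(
            c for u, v, c in g.graph.edges(data="capacity")
            if "s" in (u, v) or "t" in (u, v)
        )
        assert g.inf_capacity > total

    def test_delta_zero_inter_edges_stay_on_level(self):
        p = random_profile(np.random.default_rng(3), R=4, L=3)
        g = build_graph(p, delta_r=0)
        for u, v, c in g.graph.edges(data="capacity"):
            if c == g.inf_capacity and u[0] != v[0]:
                assert u[1] == v[1]

    def test_negative_delta_rejected(self):
        p = random_profile(np.random.default_rng(4), R=3, L=2)
        with pytest.raises(ValueError):
            build_graph(p, delta_r=-1)


class TestSolveMinCut:
    def test_all_zero_capacities_collapse(self):
        costs = np.zeros((4, 3))
        w = np.array([compute_terminal_weights(c) for c in costs])
        p = CostProfile(costs=costs, terminal_weights=w)
        cut = solve_min_cut(build_graph(p, 1))
        assert cut.cut_cost == 0
        assert (cut.k == 0).all()

    def test_delta_zero_forces_equal_levels(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = random_profile(rng, R=5, L=4)
            cut = solve_min_cut(build_graph(p, 0))
            assert len(set(cut.k.tolist())) == 1

    def test_cost_non_increasing_in_delta(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            p = random_profile(rng, R=5, L=4)
            costs = [solve_min_cut(build_graph(p, d)).cut_cost for d in range(4)]
            assert all(a >= b - 1e-9 for a, b in zip(costs, costs[1:]))

    def test_smoothness_constraint_holds(self):
        rng = np.random.default_rng(9)
        for d in (0, 1, 2):
            p = random_profile(rng, R=6, L=5)
            k = solve_min_cut(build_graph(p, d)).k
            jumps = np.abs(np.diff(np.append(k, k[0])))
            assert (jumps <= d).all()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        R=st.integers(3, 6),
        L=st.integers(2, 5),
        delta=st.integers(0, 2),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_enumeration_oracle(self, R, L, delta, seed):
        """Max-flow solution equals the exhaustive-enumeration oracle."""
        p = random_profile(np.random.default_rng(seed), R, L)
        fast = solve_min_cut(build_graph(p, delta))
        slow = brute_force_min_cut(p, delta)
        assert fast.cut_cost == pytest.approx(slow.cut_cost, abs=1e-9)
        np.testing.assert_array_equal(fast.k, slow.k)


class TestBruteForce:
    def test_minimum_property_on_explicit_vectors(self):
        rng = np.random.default_rng(11)
        p = random_profile(rng, R=3, L=3)
        best = brute_force_min_cut(p, 2)
        # enumerate a handful of feasible vectors by hand
        from uscut.graphcut import _per_ray_level_costs

        level = _per_ray_level_costs(p)
        for k in [(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3), (1, 2, 3)]:
            cost = sum(level[r, k[r]] for r in range(3))
            assert best.cut_cost <= cost + 1e-9

    def test_instance_guard(self):
        p = random_profile(np.random.default_rng(12), R=6, L=5)
        big = CostProfile(
            costs=np.tile(p.costs, (3, 10)),
            terminal_weights=np.tile(p.terminal_weights, (3, 10)),
        )
        with pytest.raises(ValueError, match="too large"):
            brute_force_min_cut(big, 1)
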