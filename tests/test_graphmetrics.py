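import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import kendall_tau_b_naive, wls_node_solve_naive
from nesfe.chemdata import AffinityTable
from nesfe.exceptions import DisconnectedMapError
from nesfe.fepmap import Edge, PerturbationMap
from nesfe.graphmetrics import (
    NodeEstimate,
    bootstrap_metric_ci,
    compute_metrics,
    cycle_closure_errors,
    experimental_null_band,
    offset_to_experiment,
    solve_node_dgs,
)
from nesfe.neswork import EdgeResult


def triangle_map():
    return PerturbationMap(
        ["A", "B", "C"],
        [Edge("A", "B", 1.0), Edge("A", "C", 1.0), Edge("B", "C", 1.0)],
    )


def edge_results(pmap, ddgs, se=0.0):
    return [
        EdgeResult(e.id, d, 0.0, d, se) for e, d in zip(pmap.edges, ddgs)
    ]


class TestSolveNodeDgs:
    def test_two_nodes_split_the_edge_symmetrically(self):
        pmap = PerturbationMap(["A", "B"], [Edge("A", "B", 1.0)])
        nodes = solve_node_dgs(pmap, edge_results(pmap, [1.0]))
        assert [n.dg_calc for n in nodes] == pytest.approx([-0.5, 0.5])

    def test_consistent_triangle_recovered_exactly(self):
        pmap = triangle_map()
        # edges in lexicographic order: A→B, A→C, B→C
        nodes = solve_node_dgs(pmap, edge_results(pmap, [1.0, 2.0, 1.0]))
        g = {n.id: n.dg_calc for n in nodes}
        assert g["B"] - g["A"] == pytest.approx(1.0, abs=1e-9)
        assert g["C"] - g["A"] == pytest.approx(2.0, abs=1e-9)

    def test_inconsistent_triangle_least_squares_solution(self):
        pmap = triangle_map()
        nodes = solve_node_dgs(pmap, edge_results(pmap, [1.0, 3.0, 1.0]))
        g = {n.id: n.dg_calc for n in nodes}
        pinned = {k: v - g["A"] for k, v in g.items()}
        assert pinned["B"] == pytest.approx(4 / 3, abs=1e-9)
        assert pinned["C"] == pytest.approx(8 / 3, abs=1e-9)

    def test_corrected_edges_close_every_cycle(self):
        pmap = triangle_map()
        nodes = solve_node_dgs(pmap, edge_results(pmap, [1.0, 3.0, 1.0]))
        g = {n.id: n.dg_calc for n in nodes}
        corrected = [
            EdgeResult(e.id, g[e.b] - g[e.a], 0.0, g[e.b] - g[e.a], 0.0)
            for e in pmap.edges
        ]
        for closure in cycle_closure_errors(pmap, corrected):
            assert closure == pytest.approx(0.0, abs=1e-9)

    def test_gauge_is_mean_zero(self):
        pmap = triangle_map()
        nodes = solve_node_dgs(pmap, edge_results(pmap, [1.0, 3.0, 1.0]))
        assert np.mean([n.dg_calc for n in nodes]) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ids = [f"n{i}" for i in range(n)]
        pairs = [(ids[i], ids[i + 1]) for i in range(n - 1)]
        extra = [
            (ids[i], ids[j])
            for i in range(n)
            for j in range(i + 2, n)
            if rng.random() < 0.4
        ]
        all_pairs = pairs + extra
        edges = [Edge(a, b, 0.5) for a, b in all_pairs]
        pmap = PerturbationMap(ids, edges)
        ddgs = rng.normal(size=len(pmap.edges))
        results = [
            EdgeResult(e.id, float(d), 0.0, float(d), float(rng.uniform(0.05, 0.6)))
            for e, d in zip(pmap.edges, ddgs)
        ]
        nodes = solve_node_dgs(pmap, results)
        oracle = wls_node_solve_naive(
            ids, [(e.a, e.b, r.ddg, r.se) for e, r in zip(pmap.edges, results)]
        )
        np.testing.assert_allclose([x.dg_calc for x in nodes], oracle, atol=1e-6)

    def test_missing_edge_result_is_an_error(self):
        pmap = triangle_map()
        with pytest.raises(ValueError, match="missing edge results"):
            solve_node_dgs(pmap, edge_results(pmap, [1.0, 2.0, 1.0])[:2])

    def test_disconnected_graph_lists_components(self):
        pmap = triangle_map()
        bad = PerturbationMap.__new__(PerturbationMap)
        bad.nodes = ["A", "B", "C", "D"]
        bad.edges = [Edge("A", "B", 1.0), Edge("C", "D", 1.0)]
        results = [EdgeResult(e.id, 0, 0, 0, 0.1) for e in bad.edges]
        with pytest.raises(DisconnectedMapError):
            solve_node_dgs(bad, results)


class TestCycleClosure:
    def test_consistent_triangle_closes(self):
        pmap = triangle_map()
        assert cycle_closure_errors(pmap, edge_results(pmap, [1.0, 2.0, 1.0])) == [
            pytest.approx(0.0)
        ]

    def test_inconsistent_triangle_signed_sum(self):
        pmap = triangle_map()
        # A→B=1, A→C=3, B→C=1: around the cycle 1 + 1 − 3 = −1
        (closure,) = cycle_closure_errors(pmap, edge_results(pmap, [1.0, 3.0, 1.0]))
        assert abs(closure) == pytest.approx(1.0)

    def test_spanning_tree_has_no_cycles(self):
        pmap = PerturbationMap(
            ["A", "B", "C"], [Edge("A", "B", 1.0), Edge("B", "C", 1.0)]
        )
        assert cycle_closure_errors(pmap, edge_results(pmap, [1.0, 1.0])) == []


class TestOffsetToExperiment:
    def test_mean_matching_shift(self):
        nodes = [NodeEstimate("a", 0.0, 0.1), NodeEstimate("b", 1.0, 0.2)]
        exp = AffinityTable({"a": (-10.0, 0.0), "b": (-9.0, 0.0)})
        out = offset_to_experiment(nodes, exp)
        assert [n.dg_calc for n in out] == pytest.approx([-10.0, -9.0])
        assert [n.se for n in out] == [0.1, 0.2]

    def test_idempotent_and_difference_preserving(self):
        nodes = [NodeEstimate("a", 0.0, 0.0), NodeEstimate("b", 2.0, 0.0),
                 NodeEstimate("c", 4.0, 0.0)]
        exp = AffinityTable({"a": (-8.0, 0.0), "b": (-6.0, 0.0)})
        once = offset_to_experiment(nodes, exp)
        assert [n.dg_calc for n in once] == pytest.approx([-8.0, -6.0, -4.0])
        twice = offset_to_experiment(once, exp)
        assert [n.dg_calc for n in twice] == pytest.approx([n.dg_calc for n in once])
        diffs = np.diff([n.dg_calc for n in once])
        np.testing.assert_allclose(diffs, np.diff([n.dg_calc for n in nodes]))

    def test_no_overlap_is_an_error(self):
        nodes = [NodeEstimate("x", 0.0, 0.0)]
        exp = AffinityTable({"a": (-8.0, 0.0)})
        with pytest.raises(ValueError, match="overlap"):
            offset_to_experiment(nodes, exp)


class TestComputeMetrics:
    def test_perfect_agreement(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.aue == 0.0 and m.rmse == 0.0
        assert m.pearson_rho == pytest.approx(1.0)
        assert m.kendall_tau == pytest.approx(1.0)

    def test_reversed_ranking_gives_tau_minus_one(self):
        exp = np.array([1.0, 2.0, 5.0, 7.0])
        m = compute_metrics(exp[::-1], exp)
        assert m.kendall_tau == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tau_matches_bruteforce_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        calc = rng.integers(0, 6, 10).astype(float)  # integer grid forces ties
        exp = rng.integers(0, 6, 10).astype(float)
        m = compute_metrics(calc, exp)
        if np.isnan(m.kendall_tau):
            assert not m.correlations_defined
        else:
            assert m.kendall_tau == pytest.approx(kendall_tau_b_naive(calc, exp))

    def test_zero_variance_flags_correlations_but_keeps_errors(self):
        m = compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not m.correlations_defined
        assert np.isnan(m.kendall_tau)
        assert m.aue == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(arrays(float, (8,), elements=st.floats(-20, 20)),
           arrays(float, (8,), elements=st.floats(-20, 20)),
           st.floats(-10, 10))
    def test_error_metrics_shift_invariant_and_ordered(self, calc, exp, c):
        m = compute_metrics(calc, exp)
        shifted = compute_metrics(calc + c, exp + c)
        # equality holds when all residuals share one magnitude; allow a ulp
        assert m.rmse >= m.aue - 1e-12 and m.aue >= 0.0
        assert shifted.aue == pytest.approx(m.aue, abs=1e-9)
        assert shifted.rmse == pytest.approx(m.rmse, abs=1e-9)

    def test_tau_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        calc, exp = rng.normal(size=12), rng.normal(size=12)
        base = compute_metrics(calc, exp).kendall_tau
        warped = compute_metrics(np.exp(calc), np.tanh(exp)).kendall_tau
        assert warped == pytest.approx(base)


class TestBootstrapCi:
    def test_perfect_agreement_gives_degenerate_rmse_ci(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ci = bootstrap_metric_ci(x, x, n_boot=200, seed=0)
        assert ci["rmse"] == (0.0, 0.0)

    def test_same_seed_reproduces_cis(self):
        rng = np.random.default_rng(1)
        calc, exp = rng.normal(size=10), rng.normal(size=10)
        assert bootstrap_metric_ci(calc, exp, 200, seed=5) == bootstrap_metric_ci(
            calc, exp, 200, seed=5
        )

    def test_point_estimate_inside_ci(self):
        rng = np.random.default_rng(2)
        exp = rng.uniform(-12, -8, 20)
        calc = exp + rng.normal(0, 0.8, 20)
        m = compute_metrics(calc, exp)
        ci = bootstrap_metric_ci(calc, exp, 1000, seed=3)
        assert ci["rmse"][0] <= m.rmse <= ci["rmse"][1]
        assert ci["kendall_tau"][0] <= m.kendall_tau <= ci["kendall_tau"][1]


class TestNullBand:
    def test_noise_free_band_is_perfect_agreement(self):
        exp = np.linspace(-12, -8, 10)
        band = experimental_null_band(exp, 0.0, 200, seed=0, floor=0.0)
        assert band["rmse"] == (0.0, 0.0)
        assert band["kendall_tau"] == pytest.approx((1.0, 1.0))

    def test_same_seed_reproduces_bands(self):
        exp = np.linspace(-12, -8, 10)
        a = experimental_null_band(exp, 0.3, 300, seed=4)
        b = experimental_null_band(exp, 0.3, 300, seed=4)
        assert a == b

    def test_rmse_band_centre_is_root_two_times_floor(self):
        # two independent noise draws of SD σ differ with SD σ√2
        exp = np.linspace(-12, -8, 30)
        band = experimental_null_band(exp, 0.0, 3000, seed=6, floor=0.43,
                                      metrics=("rmse",))
        centre = 0.5 * (band["rmse"][0] + band["rmse"][1])
        assert centre == pytest.approx(0.43 * np.sqrt(2), abs=0.06)
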