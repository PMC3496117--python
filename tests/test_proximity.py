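"""Shortest-path distances, core selection, and the permutation null."""

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from fimodules.network import FINetwork
from fimodules.proximity import (
    DistanceMatrix,
    average_linkage_core,
    mean_pairwise_distance,
    pairwise_shortest_paths,
    permutation_p,
    permutation_test,
    replace_infinite,
)


class TestPairwiseShortestPaths:
    def test_path_graph_distance(self):
        net = FINetwork.from_edges([("A", "B"), ("B", "C")])
        dm = pairwise_shortest_paths(net, ["A", "C"])
        assert dm.d[0, 1] == 2

    def test_cross_component_is_infinite(self, toy_net):
        dm = pairwise_shortest_paths(toy_net, ["A", "X"])
        assert np.isinf(dm.d[0, 1])

    def test_unknown_seed_named_in_error(self, toy_net):
        with pytest.raises(KeyError, match="NOPE"):
            pairwise_shortest_paths(toy_net, ["A", "NOPE"])

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(50, 0.08, seed=13)
        g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        net = FINetwork(g)
        nodes = sorted(g.nodes)
        seeds = [nodes[i] for i in rng.choice(len(nodes), size=10, replace=False)]
        dm = pairwise_shortest_paths(net, seeds)
        adj = nx.to_scipy_sparse_array(g, nodelist=nodes)
        full = floyd_warshall(adj, directed=False, unweighted=True)
        idx = [nodes.index(s) for s in seeds]
        assert np.array_equal(dm.d, full[np.ix_(idx, idx)])

    def test_matrix_invariants(self, toy_net):
        dm = pairwise_shortest_paths(toy_net, ["A", "B", "C", "D"])
        assert np.array_equal(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)
        finite = np.isfinite(dm.d)
        k = len(dm.seeds)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    if finite[i, j] and finite[j, l]:
                        assert dm.d[i, l] <= dm.d[i, j] + dm.d[j, l]


class TestMeanPairwiseDistance:
    def test_triangle_of_direct_neighbors(self):
        net = FINetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        dm = pairwise_shortest_paths(net, ["A", "B", "C"])
        assert mean_pairwise_distance(dm) == 1.0

    def test_simple_arithmetic(self):
        d = np.array([[0.0, 1, 2], [1, 0, 3], [2, 3, 0]])
        dm = DistanceMatrix(seeds=("A", "B", "C"), d=d)
        assert mean_pairwise_distance(dm) == pytest.approx(2.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(21)
        raw = rng.integers(1, 9, size=(6, 6)).astype(float)
        d = np.triu(raw, 1)
        d = d + d.T
        dm = DistanceMatrix(seeds=tuple("ABCDEF"), d=d)
        total = sum(
            d[i, j] for i in range(6) for j in range(i + 1, 6)
        )
        assert mean_pairwise_distance(dm) == pytest.approx(total / 15)

    def test_all_infinite_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            mean_pairwise_distance(DistanceMatrix(seeds=("A", "B"), d=d))


class TestAverageLinkageCore:
    def test_equidistant_seeds_all_retained(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        core = average_linkage_core(
            DistanceMatrix(seeds=tuple("ABCD"), d=d), coverage=0.9
        )
        assert core.retained == frozenset("ABCD")
        assert core.coverage == 1.0

    def test_outlier_excluded_at_ninety_percent(self):
        # 9 mutually adjacent seeds plus one seed far from everything
        k = 10
        d = np.full((k, k), 1.0)
        d[9, :] = 10.0
        d[:, 9] = 10.0
        np.fill_diagonal(d, 0.0)
        seeds = tuple(f"S{i}" for i in range(k))
        core = average_linkage_core(DistanceMatrix(seeds=seeds, d=d), coverage=0.9)
        assert core.retained == frozenset(seeds[:9])
        assert core.coverage == pytest.approx(0.9)

    def test_full_coverage_returns_everything(self):
        rng = np.random.default_rng(4)
        raw = rng.integers(1, 6, size=(7, 7)).astype(float)
        d = np.triu(raw, 1)
        d = d + d.T
        seeds = tuple(f"S{i}" for i in range(7))
        core = average_linkage_core(DistanceMatrix(seeds=seeds, d=d), coverage=1.0)
        assert core.retained == frozenset(seeds)

    def test_invalid_coverage_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            average_linkage_core(DistanceMatrix(seeds=("A", "B"), d=d), coverage=0.0)

    def test_infinite_entries_need_replacement(self, toy_net):
        dm = pairwise_shortest_paths(toy_net, ["A", "X"])
        with pytest.raises(ValueError, match="replace_infinite"):
            average_linkage_core(dm)
        fixed = replace_infinite(dm, toy_net)
        assert np.all(np.isfinite(fixed.d))
        # diameter of the 5-ring-with-chord component is 2 → fill value 3
        assert fixed.d[0, 1] == 3.0


class TestPermutationTest:
    def test_p_floor_is_one_over_b_plus_one(self):
        assert permutation_p(0.5, [1.0] * 999) == pytest.approx(1 / 1000)

    def test_estimator_arithmetic(self):
        assert permutation_p(2.0, [1.5, 2.0, 5.0]) == pytest.approx(3 / 4)

    def test_reproducible_under_seed(self, toy_net):
        a = permutation_test(toy_net, ["A", "C", "E"], B=50, rng_seed=42)
        b = permutation_test(toy_net, ["A", "C", "E"], B=50, rng_seed=42)
        assert a.null_values == b.null_values
        assert a.p_value == b.p_value

    def test_invariant_to_seed_ordering(self, toy_net):
        a = permutation_test(toy_net, ["A", "C", "E"], B=50, rng_seed=7)
        b = permutation_test(toy_net, ["E", "A", "C"], B=50, rng_seed=7)
        assert a.p_value == b.p_value and a.observed == b.observed

    def test_seeds_outside_component_excluded(self, toy_net):
        res = permutation_test(toy_net, ["A", "C", "X"], B=20, rng_seed=1)
        assert res.n_seeds_used == 2

    def test_invalid_b_rejected(self, toy_net):
        with pytest.raises(ValueError):
            permutation_test(toy_net, ["A", "C"], B=0, rng_seed=1)

    def test_planted_module_detected(self, default_bundle):
        _, net, truth, _, _ = default_bundle
        res = permutation_test(
            net, sorted(truth.planted_de_genes), B=200, rng_seed=3
        )
        assert res.p_value <= 0.05
        assert res.observed < float(np.mean(res.null_values))
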