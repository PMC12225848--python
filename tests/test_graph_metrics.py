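import numpy as np
import pytest

from wmdecode import (
    aggregate_regions,
    betweenness_centrality,
    clustering_coefficient,
    compute_node_metrics,
    degree_metrics,
    eigenvector_centrality,
    proportional_threshold,
    strength_metrics,
)
from wmdecode.defs import FEATURE_NAMES, METRIC_ORDER
from wmdecode.graph_metrics import ThresholdedGraph

from oracles import (
    betweenness_bruteforce,
    clustering_bruteforce,
    eigenvector_power_iteration,
)


def graph_from_edges(k, edges, weights=None):
    """edges as (source, target) pairs; matrix convention is [target, source]."""
    mask = np.zeros((k, k), dtype=int)
    w = np.zeros((k, k))
    for n, (src, tgt) in enumerate(edges):
        mask[tgt, src] = 1
        w[tgt, src] = weights[n] if weights is not None else 1.0
    return ThresholdedGraph(weights=w, mask=mask, pth=1.0,
                            density=len(edges) / (k * (k - 1)))


class TestProportionalThreshold:
    def test_keeps_three_largest_of_six(self):
        C = np.array(
            [[0.0, 0.9, 0.3], [0.8, 0.0, 0.2], [0.7, 0.1, 0.0]]
        )
        g = proportional_threshold(C, 0.5)
        assert g.mask.sum() == 3
        kept = sorted(C[g.mask.astype(bool)])
        assert kept == [0.7, 0.8, 0.9]
        assert np.all(g.weights[g.mask.astype(bool)] == C[g.mask.astype(bool)])

    def test_full_threshold_keeps_everything(self):
        rng = np.random.default_rng(0)
        C = rng.random((4, 4))
        g = proportional_threshold(C, 1.0)
        assert np.array_equal(g.mask, (~np.eye(4, dtype=bool)).astype(int))

    def test_density_consistent_across_matrices(self):
        rng = np.random.default_rng(1)
        densities = {
            proportional_threshold(rng.random((6, 6)), 0.15).density
            for _ in range(10)
        }
        assert len(densities) == 1

    def test_zero_edges_raises(self):
        with pytest.raises(ValueError, match="zero"):
            proportional_threshold(np.random.default_rng(0).random((3, 3)),
                                   0.01)

    def test_rounding_half_away_from_zero(self):
        # k=4: 12 possible edges; pth=0.125 -> 1.5 -> 2 edges
        rng = np.random.default_rng(2)
        g = proportional_threshold(rng.random((4, 4)), 0.125)
        assert g.mask.sum() == 2

    def test_tie_break_deterministic(self):
        C = np.full((3, 3), 0.5)
        g = proportional_threshold(C, 1 / 6)  # exactly one edge among ties
        # (value desc, source asc, target asc): source 0, target 1 wins
        assert g.mask[1, 0] == 1 and g.mask.sum() == 1

    def test_diagonal_never_kept(self):
        C = np.eye(5) * 10.0 + 0.01
        g = proportional_threshold(C, 0.5)
        assert np.all(np.diag(g.mask) == 0)
        assert np.all(np.diag(g.weights) == 0)


class TestDegreeMetrics:
    def test_manual_enumeration(self):
        # edges {1->2, 1->3, 2->3} with 1-based labels
        g = graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])
        in_d, out_d, d = degree_metrics(g)
        assert out_d.tolist() == [2, 1, 0]
        assert in_d.tolist() == [0, 1, 2]
        assert d.tolist() == [2, 2, 2]

    def test_empty_graph(self):
        g = graph_from_edges(4, [])
        in_d, out_d, d = degree_metrics(g)
        assert not in_d.any() and not out_d.any() and not d.any()

    def test_complete_digraph(self):
        k = 5
        edges = [(i, j) for i in range(k) for j in range(k) if i != j]
        _, _, d = degree_metrics(graph_from_edges(k, edges))
        assert np.all(d == 2 * (k - 1))


class TestStrengthMetrics:
    def test_single_edge(self):
        g = graph_from_edges(3, [(0, 1)], weights=[0.7])
        in_s, out_s, s = strength_metrics(g)
        assert out_s.tolist() == [0.7, 0.0, 0.0]
        assert in_s.tolist() == [0.0, 0.7, 0.0]

    def test_empty(self):
        in_s, out_s, s = strength_metrics(graph_from_edges(3, []))
        assert not s.any()

    def test_manual_sums(self):
        g = graph_from_edges(
            3, [(0, 1), (0, 2), (1, 2)], weights=[0.9, 0.8, 0.7]
        )
        in_s, out_s, _ = strength_metrics(g)
        assert np.allclose(out_s, [1.7, 0.7, 0.0])
        assert np.allclose(in_s, [0.0, 0.9, 1.5])


class TestClusteringCoefficient:
    def test_triangle(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (2, 0)])
        assert np.allclose(clustering_coefficient(g), 1.0)

    def test_star_has_no_triangles(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert not clustering_coefficient(g).any()

    def test_four_node_manual(self):
        # undirected links a-b, a-c, b-c, a-d
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        cc = clustering_coefficient(g)
        assert np.allclose(cc, [1 / 3, 1.0, 1.0, 0.0])

    def test_uses_symmetrized_mask(self):
        # reciprocal edges count once as an undirected link
        g1 = graph_from_edges(3, [(0, 1), (1, 2), (2, 0)])
        g2 = graph_from_edges(
            3, [(0, 1), (1, 0), (1, 2), (2, 1), (2, 0), (0, 2)]
        )
        assert np.allclose(clustering_coefficient(g1),
                           clustering_coefficient(g2))


class TestBetweennessCentrality:
    def test_directed_path(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert betweenness_centrality(g).tolist() == [0.0, 1.0, 0.0]

    def test_complete_digraph_all_zero(self):
        k = 4
        edges = [(i, j) for i in range(k) for j in range(k) if i != j]
        assert not betweenness_centrality(graph_from_edges(k, edges)).any()

    def test_out_star_hub_zero(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert not betweenness_centrality(g).any()

    def test_split_shortest_paths(self):
        # two equal-length routes 0->{1,2}->3: each middle node gets 0.5
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 3), (2, 3)])
        assert np.allclose(betweenness_centrality(g), [0, 0.5, 0.5, 0])


class TestEigenvectorCentrality:
    def test_single_edge_pair(self):
        g = graph_from_edges(4, [(0, 1)], weights=[0.5])
        ec = eigenvector_centrality(g)
        assert ec[0] == pytest.approx(1 / np.sqrt(2))
        assert ec[1] == pytest.approx(1 / np.sqrt(2))
        assert ec[2] == ec[3] == 0.0

    def test_star_hub_dominates(self):
        edges = [(0, i) for i in range(1, 5)] + [(i, 0) for i in range(1, 5)]
        ec = eigenvector_centrality(graph_from_edges(5, edges))
        assert np.allclose(ec[1:], ec[1])
        assert ec[0] == pytest.approx(np.sqrt(4) * ec[1])  # hub/leaf = sqrt(n)

    def test_satisfies_eigen_equation(self):
        rng = np.random.default_rng(3)
        W = rng.random((6, 6))
        np.fill_diagonal(W, 0.0)
        g = ThresholdedGraph(weights=W, mask=(W > 0).astype(int), pth=1.0,
                             density=1.0)
        ec = eigenvector_centrality(g)
        S = (W + W.T) / 2
        lam = ec @ S @ ec
        assert np.allclose(S @ ec, lam * ec, atol=1e-8)

    def test_zero_matrix_warns_and_returns_zero(self):
        g = graph_from_edges(3, [])
        with pytest.warns(UserWarning):
            ec = eigenvector_centrality(g)
        assert not ec.any()


class TestOracleEquivalence:
    def test_fifty_random_graphs(self):
        # brute-force path enumeration / power iteration oracles
        rng = np.random.default_rng(99)
        for _ in range(50):
            k = int(rng.integers(3, 9))
            density = rng.uniform(0.2, 0.8)
            W = rng.random((k, k)) * (rng.random((k, k)) < density)
            np.fill_diagonal(W, 0.0)
            g = ThresholdedGraph(weights=W, mask=(W > 0).astype(int),
                                 pth=1.0, density=1.0)
            metrics = compute_node_metrics(g)
            assert np.array_equal(
                metrics["in_degree"], g.mask.sum(axis=1).astype(float))
            assert np.array_equal(
                metrics["out_degree"], g.mask.sum(axis=0).astype(float))
            assert np.allclose(
                metrics["betweenness_centrality"],
                betweenness_bruteforce(g.mask), atol=1e-8)
            assert np.allclose(
                metrics["clustering_coefficient"],
                clustering_bruteforce(g.mask), atol=1e-8)
            ec_oracle = eigenvector_power_iteration(W)
            assert np.allclose(
                metrics["eigenvector_centrality"], ec_oracle, atol=1e-6)

    def test_degree_strength_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = int(rng.integers(3, 9))
            g = proportional_threshold(rng.random((k, k)),
                                       float(rng.uniform(0.1, 1.0)))
            in_d, out_d, _ = degree_metrics(g)
            in_s, out_s, _ = strength_metrics(g)
            assert in_d.sum() == out_d.sum() == g.mask.sum()
            assert in_s.sum() == pytest.approx(out_s.sum())
            assert in_s.sum() == pytest.approx(g.weights.sum())

    def test_adding_edge_is_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = 5
            W = rng.random((k, k))
            np.fill_diagonal(W, 0.0)
            mask = (rng.random((k, k)) < 0.4).astype(int)
            np.fill_diagonal(mask, 0)
            g = ThresholdedGraph(weights=W * mask, mask=mask, pth=1.0,
                                 density=1.0)
            absent = np.argwhere((mask == 0) & ~np.eye(k, dtype=bool))
            if not len(absent):
                continue
            i, j = absent[rng.integers(len(absent))]
            mask2 = mask.copy()
            mask2[i, j] = 1
            g2 = ThresholdedGraph(weights=W * mask2, mask=mask2, pth=1.0,
                                  density=1.0)
            for before, after in zip(degree_metrics(g), degree_metrics(g2)):
                assert np.all(after >= before)
            for before, after in zip(strength_metrics(g), strength_metrics(g2)):
                assert np.all(after >= before - 1e-12)


class TestAggregateRegions:
    REGIONS = ["MTL", "MTL", "PFC", "OFC"]

    def _metrics(self, k=4):
        rng = np.random.default_rng(0)
        return {m: rng.random(k) for m in METRIC_ORDER}

    def test_vector_length_27(self):
        vec = aggregate_regions(self._metrics(), self.REGIONS)
        assert vec.shape == (27,)
        assert len(FEATURE_NAMES) == 27

    def test_single_channel_region_passthrough(self):
        metrics = self._metrics()
        vec = aggregate_regions(metrics, self.REGIONS)
        # PFC = channel 2 only; PFC block is features 9..17
        for m_idx, metric in enumerate(METRIC_ORDER):
            assert vec[9 + m_idx] == metrics[metric][2]

    def test_region_mean(self):
        metrics = {m: np.zeros(4) for m in METRIC_ORDER}
        metrics["degree"] = np.array([2.0, 4.0, 0.0, 0.0])
        vec = aggregate_regions(metrics, self.REGIONS)
        assert vec[FEATURE_NAMES.index("MTL.degree")] == 3.0

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="OFC"):
            aggregate_regions(self._metrics(3), ["MTL", "MTL", "PFC"])

    def test_feature_name_order(self):
        assert FEATURE_NAMES[0] == "MTL.degree"
        assert FEATURE_NAMES[9] == "PFC.degree"
        assert FEATURE_NAMES[-1] == "OFC.eigenvector_centrality"
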