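"""Node metrics against hand computations and brute-force oracles."""

import math

import numpy as np
import pytest

import oracles
from conftest import digraph_from
from msgnet.metrics import (
    DistanceConvention,
    betweenness_centrality,
    closeness_centrality,
    degrees,
    eigenvector_centrality,
    local_clustering,
    node_metric_table,
    shortest_path_distances,
)


def metrics_vs_oracles(n, edges):
    """Compare all six metrics on one {(u, v): w} digraph."""
    g = digraph_from(edges)
    g.add_nodes_from(range(n))
    lengths = {e: 1.0 / w for e, w in edges.items()}

    deg = degrees(g)
    a = oracles.adjacency(n, edges)
    assert np.array_equal(deg["indegree"].to_numpy(), (a > 0).sum(axis=0))
    assert np.array_equal(deg["outdegree"].to_numpy(), (a > 0).sum(axis=1))

    dist = shortest_path_distances(g).to_numpy()
    expected = oracles.floyd_warshall(n, lengths)
    assert np.allclose(dist, expected, atol=1e-9)

    close = closeness_centrality(g).to_numpy()
    assert np.allclose(close, oracles.closeness_incoming(expected), atol=1e-9)

    eig = eigenvector_centrality(g).to_numpy()
    ref = oracles.dominant_eigenvector(oracles.adjacency(n, edges).T)
    assert np.allclose(eig, ref, atol=1e-6)

    btw = betweenness_centrality(g).to_numpy()
    assert np.allclose(btw, oracles.betweenness(n, lengths), atol=1e-6)

    clus = local_clustering(g).to_numpy()
    und = {(min(u, v), max(u, v)) for u, v in edges}
    assert np.allclose(clus, oracles.local_clustering(n, und), atol=1e-12)


class TestDegrees:
    def test_star_center(self):
        g = digraph_from({(0, i): 1 for i in range(1, 5)})
        deg = degrees(g)
        assert deg.loc[0, "outdegree"] == 4
        assert deg.loc[0, "indegree"] == 0

    def test_reciprocated_pair(self):
        g = digraph_from({(0, 1): 3, (1, 0): 9})
        deg = degrees(g)
        assert (deg["indegree"] == 1).all()
        assert (deg["outdegree"] == 1).all()

    def test_matches_adjacency_sums_on_random_graph(self):
        rng = np.random.default_rng(1)
        n = 30
        edges = {
            (int(u), int(v)): float(rng.integers(1, 10))
            for u, v in rng.integers(0, n, size=(150, 2))
            if u != v
        }
        g = digraph_from(edges)
        g.add_nodes_from(range(n))
        a = oracles.adjacency(n, edges)
        deg = degrees(g)
        assert np.array_equal(deg["indegree"].to_numpy(), (a > 0).sum(axis=0))
        assert np.array_equal(deg["outdegree"].to_numpy(), (a > 0).sum(axis=1))


class TestDistances:
    def test_single_edge_inverse_weight(self):
        g = digraph_from({(0, 1): 4})
        dist = shortest_path_distances(g)
        assert dist.loc[0, 1] == pytest.approx(0.25)
        assert math.isinf(dist.loc[1, 0])

    def test_tied_paths_same_length(self):
        # 0->1->2 at 1/2+1/2 equals direct 0->2 at 1/1
        g = digraph_from({(0, 1): 2, (1, 2): 2, (0, 2): 1})
        dist = shortest_path_distances(g)
        assert dist.loc[0, 2] == pytest.approx(1.0)

    def test_hop_and_direct_conventions(self):
        g = digraph_from({(0, 1): 5, (1, 2): 7})
        direct = shortest_path_distances(g, DistanceConvention.DIRECT_WEIGHT)
        hop = shortest_path_distances(g, DistanceConvention.HOP)
        assert direct.loc[0, 2] == 12
        assert hop.loc[0, 2] == 2

    def test_nonpositive_weight_fatal(self):
        g = digraph_from({(0, 1): 0})
        with pytest.raises(ValueError, match="positive"):
            shortest_path_distances(g)

    def test_matches_floyd_warshall_on_random_digraphs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n, edges = oracles.random_digraph(rng, n_min=4, n_max=7)
            g = digraph_from(edges)
            g.add_nodes_from(range(n))
            dist = shortest_path_distances(g).to_numpy()
            ref = oracles.floyd_warshall(n, {e: 1.0 / w for e, w in edges.items()})
            assert np.allclose(dist, ref, atol=1e-9)


class TestCloseness:
    def test_directed_line_incoming(self):
        # 0 -> 1 -> 2, unit weights: closeness(2) = 2 / (1 + 2)
        g = digraph_from({(0, 1): 1, (1, 2): 1})
        close = closeness_centrality(g)
        assert close[2] == pytest.approx(2 / 3)
        assert close[0] == 0.0

    def test_isolated_node_zero(self):
        g = digraph_from({(0, 1): 1})
        g.add_node(2)
        assert closeness_centrality(g)[2] == 0.0

    def test_outgoing_direction(self):
        g = digraph_from({(0, 1): 1, (1, 2): 1})
        out = closeness_centrality(g, direction="outgoing")
        assert out[0] == pytest.approx(2 / 3)
        assert out[2] == 0.0


class TestEigenvector:
    def test_symmetric_triangle_uniform(self):
        edges = {(u, v): 5 for u in range(3) for v in range(3) if u != v}
        eig = eigenvector_centrality(digraph_from(edges))
        assert np.allclose(eig.to_numpy(), 1 / np.sqrt(3), atol=1e-9)

    def test_mass_concentrates_on_heavy_component(self):
        g = digraph_from({(0, 1): 10, (1, 0): 10, (2, 3): 1, (3, 2): 1})
        eig = eigenvector_centrality(g)
        assert eig[0] > 0.7 and eig[1] > 0.7
        assert eig[2] < 1e-6 and eig[3] < 1e-6

    def test_matches_dense_eigensolver_on_strongly_connected_graph(self):
        rng = np.random.default_rng(3)
        n = 10
        # a directed cycle guarantees strong connectivity and aperiodicity
        # is forced by the extra random chords
        edges = {(i, (i + 1) % n): float(rng.integers(1, 10)) for i in range(n)}
        for _ in range(25):
            u, v = rng.integers(0, n, 2)
            if u != v:
                edges[(int(u), int(v))] = float(rng.integers(1, 10))
        g = digraph_from(edges)
        eig = eigenvector_centrality(g).to_numpy()
        ref = oracles.dominant_eigenvector(oracles.adjacency(n, edges).T)
        assert np.allclose(eig, ref, atol=1e-6)


class TestBetweenness:
    def test_directed_path_middle_node(self):
        g = digraph_from({(0, 1): 1, (1, 2): 1})
        btw = betweenness_centrality(g)
        assert btw[1] == pytest.approx(1.0)
        assert btw[0] == btw[2] == 0.0

    def test_complete_triangle_no_intermediaries(self):
        edges = {(u, v): 2 for u in range(3) for v in range(3) if u != v}
        assert (betweenness_centrality(digraph_from(edges)) == 0).all()

    def test_split_shortest_paths(self):
        # two equal-length 0->3 routes via 1 and 2: each carries 1/2
        g = digraph_from({(0, 1): 1, (1, 3): 1, (0, 2): 1, (2, 3): 1})
        btw = betweenness_centrality(g)
        assert btw[1] == pytest.approx(0.5)
        assert btw[2] == pytest.approx(0.5)


class TestClustering:
    def test_triangle_projection(self):
        g = digraph_from({(0, 1): 1, (1, 2): 1, (2, 0): 1})
        assert (local_clustering(g) == 1.0).all()

    def test_star_center_zero(self):
        g = digraph_from({(0, i): 1 for i in range(1, 5)})
        assert (local_clustering(g) == 0.0).all()

    def test_matches_enumeration_on_random_graph(self):
        rng = np.random.default_rng(4)
        n = 20
        edges = {
            (int(u), int(v)): 1.0
            for u, v in rng.integers(0, n, size=(60, 2))
            if u != v
        }
        g = digraph_from(edges)
        g.add_nodes_from(range(n))
        und = {(min(u, v), max(u, v)) for u, v in edges}
        assert np.allclose(
            local_clustering(g).to_numpy(), oracles.local_clustering(n, und), atol=1e-12
        )


class TestProperties:
    def test_all_metrics_match_oracles_on_small_digraphs(self):
        """Spot sample of the exhaustive oracle suite (full run in acceptance)."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, edges = oracles.random_digraph(rng, require_simple_dominant=True)
            metrics_vs_oracles(n, edges)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        n, edges = oracles.random_digraph(rng, n_min=5, n_max=6, require_simple_dominant=True)
        g = digraph_from(edges)
        g.add_nodes_from(range(n))
        perm = rng.permutation(n)
        relabeled = digraph_from({(int(perm[u]), int(perm[v])): w for (u, v), w in edges.items()})
        relabeled.add_nodes_from(range(n))
        t1 = node_metric_table(g)
        t2 = node_metric_table(relabeled)
        for node in range(n):
            assert np.allclose(
                t1.loc[node].to_numpy(), t2.loc[int(perm[node])].to_numpy(), atol=1e-8
            )

    def test_adding_edge_never_decreases_outdegree(self):
        g = digraph_from({(0, 1): 1, (1, 2): 1})
        before = degrees(g).loc[0, "outdegree"]
        g.add_edge(0, 2, weight=1)
        after = degrees(g).loc[0, "outdegree"]
        assert after >= before
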