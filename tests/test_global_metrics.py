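"""Global metrics against hand values and enumeration oracles."""

import numpy as np
import pytest

import oracles
from conftest import digraph_from
from msgnet.errors import UndefinedMetricError
from msgnet.global_metrics import (
    assortativity_categorical,
    assortativity_degree,
    density,
    global_metric_report,
    reciprocity,
    transitivity,
    weighted_diameter,
)
from msgnet.metrics import DistanceConvention


class TestDensity:
    def test_complete_directed_triangle(self):
        assert density(3, 6) == 1.0

    def test_no_edges(self):
        assert density(5, 0) == 0.0

    def test_single_node_undefined(self):
        with pytest.raises(UndefinedMetricError):
            density(1, 0)

    def test_exact_rational_arithmetic_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 10_000))
            e = int(rng.integers(0, n * (n - 1) + 1))
            # big-integer cross-multiplication: density * N(N-1) == E exactly
            assert density(n, e) * n * (n - 1) == pytest.approx(e, rel=1e-12)


class TestReciprocity:
    def test_fully_reciprocated(self):
        g = digraph_from({(0, 1): 1, (1, 0): 1, (1, 2): 1, (2, 1): 1})
        assert reciprocity(g) == 1.0

    def test_two_of_three(self):
        g = digraph_from({(0, 1): 1, (1, 0): 1, (0, 2): 1})
        assert reciprocity(g) == pytest.approx(2 / 3)

    def test_one_way_edge(self):
        assert reciprocity(digraph_from({(0, 1): 1})) == 0.0

    def test_edgeless_undefined(self):
        g = digraph_from({})
        g.add_nodes_from([0, 1])
        with pytest.raises(UndefinedMetricError):
            reciprocity(g)


class TestDiameter:
    def test_single_edge_direct(self):
        assert weighted_diameter(digraph_from({(0, 1): 5})) == 5.0

    def test_line_direct(self):
        assert weighted_diameter(digraph_from({(0, 1): 3, (1, 2): 4})) == 7.0

    def test_inverse_convention(self):
        g = digraph_from({(0, 1): 4})
        assert weighted_diameter(g, DistanceConvention.INVERSE_WEIGHT) == 0.25

    def test_no_reachable_pair_undefined(self):
        g = digraph_from({})
        g.add_nodes_from([0, 1])
        with pytest.raises(UndefinedMetricError):
            weighted_diameter(g)

    def test_matches_floyd_warshall_max(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n, edges = oracles.random_digraph(rng, n_min=4, n_max=7)
            g = digraph_from(edges)
            g.add_nodes_from(range(n))
            dist = oracles.floyd_warshall(n, dict(edges))
            finite = [
                dist[i, j]
                for i in range(n)
                for j in range(n)
                if i != j and np.isfinite(dist[i, j])
            ]
            if not finite:
                continue
            assert weighted_diameter(g) == pytest.approx(max(finite))


class TestTransitivity:
    def test_triangle(self):
        assert transitivity(digraph_from({(0, 1): 1, (1, 2): 1, (2, 0): 1})) == 1.0

    def test_path_of_three(self):
        assert transitivity(digraph_from({(0, 1): 1, (1, 2): 1})) == 0.0

    def test_matches_triple_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n, edges = oracles.random_digraph(rng, n_min=4, n_max=8)
            g = digraph_from(edges)
            g.add_nodes_from(range(n))
            und = {(min(u, v), max(u, v)) for u, v in edges}
            assert transitivity(g) == pytest.approx(oracles.transitivity(n, und))


class TestCategoricalAssortativity:
    def test_two_isolated_blocks_fully_assortative(self):
        g = digraph_from({(0, 1): 1, (1, 0): 1, (2, 3): 1, (3, 2): 1})
        cats = {0: "x", 1: "x", 2: "y", 3: "y"}
        assert assortativity_categorical(g, cats) == 1.0

    def test_balanced_bipartite_negative(self):
        edges = {(0, 2): 1, (2, 0): 1, (0, 3): 1, (3, 1): 1, (1, 2): 1, (2, 1): 1}
        g = digraph_from(edges)
        cats = {0: "x", 1: "x", 2: "y", 3: "y"}
        r = assortativity_categorical(g, cats)
        assert r < 0
        assert r == pytest.approx(oracles.categorical_assortativity(list(edges), cats))

    def test_matches_mixing_matrix_oracle_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, edges = oracles.random_digraph(rng, n_min=4, n_max=8)
            cats = {i: ("x" if rng.random() < 0.5 else "y") for i in range(n)}
            if len(set(cats.values())) < 2:
                continue
            g = digraph_from(edges)
            g.add_nodes_from(range(n))
            assert assortativity_categorical(g, cats) == pytest.approx(
                oracles.categorical_assortativity(list(edges), cats)
            )

    def test_single_category_undefined(self):
        g = digraph_from({(0, 1): 1})
        with pytest.raises(UndefinedMetricError):
            assortativity_categorical(g, {0: "x", 1: "x"})

    def test_bounds_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n, edges = oracles.random_digraph(rng, n_min=4, n_max=8)
            g = digraph_from(edges)
            g.add_nodes_from(range(n))
            cats = {i: ("x" if i % 2 else "y") for i in range(n)}
            r = assortativity_categorical(g, cats)
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
            assert 0.0 <= transitivity(g) <= 1.0
            assert 0.0 <= reciprocity(g) <= 1.0


class TestDegreeAssortativity:
    def test_regular_graph_undefined(self):
        # directed 4-cycle: every total degree equals 2
        g = digraph_from({(0, 1): 1, (1, 2): 1, (2, 3): 1, (3, 0): 1})
        with pytest.raises(UndefinedMetricError):
            assortativity_degree(g)

    def test_star_strongly_negative_matches_pearson(self):
        g = digraph_from({(0, i): 1 for i in range(1, 8)})
        total = {n: g.in_degree(n) + g.out_degree(n) for n in g.nodes}
        x = [total[u] for u, _ in g.edges]
        y = [total[v] for _, v in g.edges]
        # all sources are the hub, so source degrees are constant
        assert np.std(x) == 0
        with pytest.raises(UndefinedMetricError):
            assortativity_degree(g)

    def test_matches_edge_list_correlation_oracle(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 15:
            n, edges = oracles.random_digraph(rng, n_min=5, n_max=8)
            g = digraph_from(edges)
            g.add_nodes_from(range(n))
            total = {v: g.in_degree(v) + g.out_degree(v) for v in g.nodes}
            x = np.array([total[u] for u, _ in g.edges], dtype=float)
            y = np.array([total[v] for _, v in g.edges], dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            assert assortativity_degree(g) == pytest.approx(float(np.corrcoef(x, y)[0, 1]))
            checked += 1


def test_report_collects_all_metrics(toy_events):
    from msgnet.graph import build_network

    g = build_network(toy_events)
    report = global_metric_report(g, {"letter": {n: n for n in g.nodes}})
    assert set(report) >= {"density", "reciprocity", "diameter", "transitivity", "assortativity"}
    assert report["density"] == pytest.approx(3 / 6)
    assert report["reciprocity"] == pytest.approx(2 / 3)
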