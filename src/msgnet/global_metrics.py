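"""Whole-network metrics: density, reciprocity, diameter, transitivity,
assortativity (categorical and by degree).

Density, reciprocity, transitivity, and assortativity ignore edge
weights; the diameter sums weights along shortest paths (direct weights
by default, inverse-weight available to match the node-centrality
convention).
"""

from __future__ import annotations

from typing import Mapping, Optional

import networkx as nx
import numpy as np

from .errors import UndefinedMetricError
from .metrics import DistanceConvention, shortest_path_distances


def density(n_nodes: int, n_edges: int) -> float:
    """Directed density E / (N (N-1)), no self-loops."""
    if n_nodes < 2:
        raise UndefinedMetricError("density undefined for fewer than 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1))


def reciprocity(graph: nx.DiGraph) -> float:
    """Fraction of directed edges whose reverse edge also exists."""
    m = graph.number_of_edges()
    if m == 0:
        raise UndefinedMetricError("reciprocity undefined on an edgeless graph")
    reciprocated = sum(1 for u, v in graph.edges if graph.has_edge(v, u))
    return reciprocated / m


def weighted_diameter(
    graph: nx.DiGraph,
    convention: DistanceConvention = DistanceConvention.DIRECT_WEIGHT,
) -> float:
    """Longest shortest-path distance over ordered reachable pairs.

    Unreachable pairs are ignored, so the statistic is defined on
    weakly connected digraphs; with no reachable pair at all it is
    undefined.
    """
    if graph.number_of_nodes() == 0:
        raise UndefinedMetricError("diameter undefined on the empty graph")
    dist = shortest_path_distances(graph, convention).to_numpy(copy=True)
    np.fill_diagonal(dist, -np.inf)
    finite = np.isfinite(dist)
    if not finite.any():
        raise UndefinedMetricError("no reachable pair of distinct nodes")
    return float(dist[finite].max())


def transitivity(graph: nx.DiGraph) -> float:
    """Global transitivity 3·triangles / connected triples on the
    undirected projection; 0 when there are no connected triples."""
    return nx.transitivity(nx.Graph(graph))


def assortativity_categorical(graph: nx.DiGraph, attribute: Mapping[str, str] | str) -> float:
    """Newman's assortativity for a categorical node attribute.

    ``attribute`` is either a node->category mapping or the name of a
    node attribute on the graph.  Computed from the directed,
    unweighted edge mixing matrix e as
    r = (Σᵢ eᵢᵢ − Σᵢ aᵢ bᵢ) / (1 − Σᵢ aᵢ bᵢ), with r = 1 on a
    perfectly assortative graph.
    """
    if isinstance(attribute, str):
        attribute = nx.get_node_attributes(graph, attribute)
    categories = sorted({attribute[n] for n in graph.nodes})
    if len(categories) < 2:
        raise UndefinedMetricError("assortativity needs at least 2 categories present")
    if graph.number_of_edges() == 0:
        raise UndefinedMetricError("assortativity undefined on an edgeless graph")
    index = {c: i for i, c in enumerate(categories)}
    e = np.zeros((len(categories), len(categories)))
    for u, v in graph.edges:
        e[index[attribute[u]], index[attribute[v]]] += 1.0
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    trace = np.trace(e)
    ab = float(a @ b)
    if trace == 1.0:
        return 1.0
    return (trace - ab) / (1.0 - ab)


def assortativity_degree(graph: nx.DiGraph) -> float:
    """Pearson correlation of total degree (in+out) across directed edges."""
    if graph.number_of_edges() < 2:
        raise UndefinedMetricError("degree assortativity needs at least 2 edges")
    total = {n: graph.in_degree(n) + graph.out_degree(n) for n in graph.nodes}
    x = np.array([total[u] for u, _ in graph.edges], dtype=float)
    y = np.array([total[v] for _, v in graph.edges], dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedMetricError("degree assortativity undefined: zero degree variance")
    return float(np.corrcoef(x, y)[0, 1])


def global_metric_report(
    graph: nx.DiGraph,
    attributes: Optional[dict[str, Mapping[str, str]]] = None,
    diameter_convention: DistanceConvention = DistanceConvention.DIRECT_WEIGHT,
) -> dict:
    """The five global metrics as one JSON-ready dict.

    ``attributes`` maps attribute names (e.g. ``location``, ``role``)
    to node->category mappings; metrics that are undefined on the given
    graph are reported as None.
    """
    report: dict = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "conventions": {"diameter": diameter_convention.value},
    }

    def attempt(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetricError:
            return None

    report["density"] = attempt(density, graph.number_of_nodes(), graph.number_of_edges())
    report["reciprocity"] = attempt(reciprocity, graph)
    report["diameter"] = attempt(weighted_diameter, graph, diameter_convention)
    report["transitivity"] = transitivity(graph) if graph.number_of_nodes() else None
    report["assortativity"] = {}
    if attributes:
        for name, mapping in attributes.items():
            report["assortativity"][name] = attempt(assortativity_categorical, graph, mapping)
    report["assortativity"]["total_degree"] = attempt(assortativity_degree, graph)
    return report
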