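"""Node-level network metrics for the messaging digraph.

Six per-professional metrics: indegree, outdegree, closeness,
eigenvector, and betweenness centrality, and the local clustering
coefficient.  Degrees and clustering ignore edge weights; closeness and
betweenness run on inverse-weight path lengths (an edge carrying more
characters is a *shorter* hop), and eigenvector centrality uses the raw
weights.  Heavy shortest-path work is delegated to igraph's C core;
eigenvector centrality is a plain power iteration on the sparse
adjacency.
"""

from __future__ import annotations

from enum import Enum
from typing import Literal

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConvergenceError


class DistanceConvention(str, Enum):
    """How an edge weight enters a path length.

    ``inverse_weight`` (1/weight per edge) is the convention for the
    node centralities: heavier communication = closer.  ``direct_weight``
    sums raw weights (used for the network diameter); ``hop`` ignores
    weights.
    """

    INVERSE_WEIGHT = "inverse_weight"
    DIRECT_WEIGHT = "direct_weight"
    HOP = "hop"


def _node_order(graph: nx.DiGraph) -> list:
    return sorted(graph.nodes)


def _to_igraph(graph: nx.DiGraph, nodes: list) -> tuple[ig.Graph, list[float]]:
    index = {n: i for i, n in enumerate(nodes)}
    edges, weights = [], []
    for u, v, data in sorted(graph.edges(data=True)):
        edges.append((index[u], index[v]))
        weights.append(float(data["weight"]))
    g = ig.Graph(n=len(nodes), edges=edges, directed=True)
    return g, weights


def _edge_lengths(weights: list[float], convention: DistanceConvention):
    if any(w <= 0 for w in weights):
        raise ValueError("edge weights must be positive")
    if convention == DistanceConvention.INVERSE_WEIGHT:
        return [1.0 / w for w in weights]
    if convention == DistanceConvention.DIRECT_WEIGHT:
        return list(weights)
    return None  # hop: unweighted


def degrees(graph: nx.DiGraph) -> pd.DataFrame:
    """Unweighted in/outdegree per node (edge = distinct partner)."""
    nodes = _node_order(graph)
    return pd.DataFrame(
        {
            "indegree": [graph.in_degree(n) for n in nodes],
            "outdegree": [graph.out_degree(n) for n in nodes],
        },
        index=pd.Index(nodes, name="node_id"),
    )


def shortest_path_distances(
    graph: nx.DiGraph,
    convention: DistanceConvention = DistanceConvention.INVERSE_WEIGHT,
) -> pd.DataFrame:
    """All-pairs shortest-path distances (Dijkstra); unreachable = inf.

    Row = source, column = target, in sorted node order.
    """
    nodes = _node_order(graph)
    if not nodes:
        return pd.DataFrame()
    g, weights = _to_igraph(graph, nodes)
    lengths = _edge_lengths(weights, DistanceConvention(convention))
    mat = np.asarray(g.distances(weights=lengths, mode="out"), dtype=float)
    return pd.DataFrame(mat, index=pd.Index(nodes, name="source"), columns=nodes)


def closeness_centrality(
    graph: nx.DiGraph,
    convention: DistanceConvention = DistanceConvention.INVERSE_WEIGHT,
    direction: Literal["incoming", "outgoing"] = "incoming",
) -> pd.Series:
    """Reachable-set closeness: (|R|-1) / sum of distances over R.

    ``incoming`` (default) sums d(y, x) over the nodes y that can reach
    x — how quickly information funnels *to* a professional.  Nodes
    reached by at most themselves get 0.  On graphs with unreachable
    pairs the sum runs over the reachable set only, which keeps the
    statistic defined on weakly connected digraphs.
    """
    dist = shortest_path_distances(graph, convention)
    if dist.empty:
        return pd.Series(dtype=float, name="closeness")
    mat = dist.to_numpy(copy=True)
    np.fill_diagonal(mat, np.inf)
    if direction == "incoming":
        mat = mat.T  # row x now holds d(y, x) over sources y
    finite = np.isfinite(mat)
    n_reach = finite.sum(axis=1)
    totals = np.where(finite, mat, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where((n_reach > 0) & (totals > 0), n_reach / totals, 0.0)
    return pd.Series(values, index=dist.index.rename("node_id"), name="closeness")


def eigenvector_centrality(
    graph: nx.DiGraph,
    direction: Literal["incoming", "outgoing"] = "incoming",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.Series:
    """Weighted eigenvector centrality by power iteration.

    ``incoming`` solves x_i ∝ Σ_j w_ji x_j (influence accrues from
    being messaged by central nodes); ``outgoing`` transposes.  The
    returned vector is nonnegative with unit Euclidean norm.  Raises
    :class:`ConvergenceError` if the L2 change has not fallen below
    ``tol`` within ``max_iter`` iterations.
    """
    nodes = _node_order(graph)
    n = len(nodes)
    if n == 0:
        raise ValueError("eigenvector centrality undefined on the empty graph")
    index = {node: i for i, node in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, data in graph.edges(data=True):
        rows.append(index[u])
        cols.append(index[v])
        vals.append(float(data["weight"]))
    w = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    op = w.T if direction == "incoming" else w
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        x_new = op @ x
        norm = np.linalg.norm(x_new)
        if norm == 0.0:
            # nilpotent adjacency (e.g. a DAG): centrality mass vanishes
            x_new = np.zeros(n)
            return pd.Series(x_new, index=pd.Index(nodes, name="node_id"), name="eigenvector")
        x_new /= norm
        if np.linalg.norm(x_new - x) < tol:
            return pd.Series(x_new, index=pd.Index(nodes, name="node_id"), name="eigenvector")
        x = x_new
    raise ConvergenceError(f"power iteration did not converge within {max_iter} iterations")


def betweenness_centrality(
    graph: nx.DiGraph,
    convention: DistanceConvention = DistanceConvention.INVERSE_WEIGHT,
) -> pd.Series:
    """Unnormalized directed betweenness on inverse-weight shortest paths.

    For each node v, the sum over ordered pairs (s, t) of the fraction
    of shortest s→t paths passing through v.  Left unnormalized: raw
    path counts are the scale on which hub brokerage is reported.
    """
    nodes = _node_order(graph)
    if not nodes:
        return pd.Series(dtype=float, name="betweenness")
    g, weights = _to_igraph(graph, nodes)
    lengths = _edge_lengths(weights, DistanceConvention(convention))
    values = g.betweenness(directed=True, weights=lengths)
    return pd.Series(
        np.asarray(values, dtype=float), index=pd.Index(nodes, name="node_id"), name="betweenness"
    )


def local_clustering(graph: nx.DiGraph) -> pd.Series:
    """Local clustering coefficient on the undirected, unweighted projection.

    c(v) = (edges among v's neighbors) / (pairs of neighbors); nodes
    with fewer than two neighbors get 0.
    """
    nodes = _node_order(graph)
    undirected = nx.Graph(graph)
    values = nx.clustering(undirected)
    return pd.Series(
        [values.get(n, 0.0) for n in nodes],
        index=pd.Index(nodes, name="node_id"),
        name="clustering_coefficient",
    )


METRIC_COLUMNS = (
    "indegree",
    "outdegree",
    "closeness",
    "eigenvector",
    "betweenness",
    "clustering_coefficient",
)


def node_metric_table(
    graph: nx.DiGraph,
    convention: DistanceConvention = DistanceConvention.INVERSE_WEIGHT,
    direction: Literal["incoming", "outgoing"] = "incoming",
) -> pd.DataFrame:
    """All six node metrics as one table (sorted node index)."""
    table = degrees(graph)
    table["closeness"] = closeness_centrality(graph, convention, direction)
    table["eigenvector"] = eigenvector_centrality(graph, direction)
    table["betweenness"] = betweenness_centrality(graph, convention)
    table["clustering_coefficient"] = local_clustering(graph)
    return table
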