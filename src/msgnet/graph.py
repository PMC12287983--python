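"""Build the directed weighted messaging network and extract its GCC.

Nodes are professionals, a directed edge u->v exists when u sent at
least one nonempty message to v, its weight is the summed character
length of those messages, and ``message_count`` rides along as
metadata.  A pair of professionals can therefore share at most two
edges (one per direction).  The giant connected component (GCC) is the
largest weakly connected component — reachability ignoring direction.
"""

from __future__ import annotations

import csv
from typing import Mapping, Optional, Sequence

import networkx as nx

from .errors import UndefinedMetricError
from .events import MessageEvent, Professional


def build_network(
    events: Sequence[MessageEvent],
    roster: Optional[Mapping[str, Professional]] = None,
) -> nx.DiGraph:
    """Aggregate cleaned events into the messaging digraph.

    Every message endpoint becomes a node (isolated receivers are
    discarded later by the GCC step); ``roster`` attributes (role,
    location) are attached when given.  Zero-length messages must have
    been removed upstream — a weight-0 edge has no inverse-weight
    distance.
    """
    g = nx.DiGraph()
    for e in events:
        if e.char_length <= 0:
            raise ValueError("zero-length message reached build_network; clean events first")
        if g.has_edge(e.sender_id, e.receiver_id):
            data = g[e.sender_id][e.receiver_id]
            data["weight"] += e.char_length
            data["message_count"] += 1
        else:
            g.add_edge(e.sender_id, e.receiver_id, weight=e.char_length, message_count=1)
    if roster is not None:
        for node in g.nodes:
            prof = roster.get(node)
            if prof is not None:
                g.nodes[node]["role"] = prof.role
                g.nodes[node]["location"] = prof.location
    return g


def giant_connected_component(graph: nx.DiGraph) -> nx.DiGraph:
    """Largest weakly connected component, as a copied subgraph.

    Size ties are broken toward the component containing the smallest
    node id, so extraction is deterministic; the GCC of a GCC is
    itself.
    """
    if graph.number_of_nodes() == 0:
        return graph.copy()
    components = list(nx.weakly_connected_components(graph))
    max_size = max(len(c) for c in components)
    best = min(
        (c for c in components if len(c) == max_size),
        key=lambda c: min(map(str, c)),
    )
    return graph.subgraph(best).copy()


def gcc_coverage(
    total_nodes: int, total_edges: int, gcc_nodes: int, gcc_edges: int
) -> tuple[float, float]:
    """GCC share of nodes and edges, as percentages rounded to 1 decimal."""
    if total_nodes <= 0 or total_edges <= 0:
        raise UndefinedMetricError("coverage undefined for empty totals")
    if gcc_nodes > total_nodes or gcc_edges > total_edges:
        raise ValueError("GCC counts exceed totals")
    return (
        round(100.0 * gcc_nodes / total_nodes, 1),
        round(100.0 * gcc_edges / total_edges, 1),
    )


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(path)


def write_edgelist_csv(graph: nx.DiGraph, path) -> None:
    """Weighted edge list: source,target,weight,message_count."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight", "message_count"])
        for u, v, data in sorted(graph.edges(data=True)):
            writer.writerow([u, v, data["weight"], data.get("message_count", "")])


def read_edgelist_csv(path) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            count = row.get("message_count")
            g.add_edge(
                row["source"],
                row["target"],
                weight=int(row["weight"]),
                message_count=int(count) if count else 0,
            )
    return g
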