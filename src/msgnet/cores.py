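"""Quartile-based outdegree core hierarchy.

Nodes are binned into four hierarchical cores by where their outdegree
falls relative to the 25th, 50th, and 75th percentiles of the GCC
outdegree distribution: core 1 (most central) holds nodes at or above
the 75th percentile, core 4 the bottom quartile.  This is quantile
binning, not iterative k-core peeling; a classical peeling variant is
provided separately for comparison but is not part of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .events import Professional


@dataclass
class CoreAssignment:
    """Node -> core (1..4) plus the outdegree cut points used."""

    cores: pd.Series          # index node_id, values in {1,2,3,4}
    cut_points: tuple[float, float, float]   # (q25, q50, q75)


def compute_cut_points(
    outdegrees: Sequence[int], method: str = "inverted_cdf"
) -> tuple[float, float, float]:
    """(q25, q50, q75) of the outdegrees.

    Default is the nearest-rank (type-1 / inverted CDF) quantile, so
    every cut point is an outdegree that actually occurs; any numpy
    quantile method can be requested instead.
    """
    values = np.asarray(list(outdegrees))
    if values.size < 4:
        raise ValueError("need at least 4 outdegrees to form quartiles")
    q25, q50, q75 = np.quantile(values, [0.25, 0.50, 0.75], method=method)
    return float(q25), float(q50), float(q75)


def assign_cores(
    outdegrees: Mapping[str, int], cut_points: tuple[float, float, float]
) -> CoreAssignment:
    """Bin each node by its outdegree: at/above q75 -> core 1,
    [q50, q75) -> core 2, [q25, q50) -> core 3, below q25 -> core 4.

    "At or above" binds to the highest qualifying core, so when cut
    points coincide the lower cores collapse to empty.
    """
    q25, q50, q75 = cut_points
    if not q25 <= q50 <= q75:
        raise ValueError("cut points must be nondecreasing")
    nodes = sorted(outdegrees)
    values = np.array([outdegrees[n] for n in nodes], dtype=float)
    cores = np.where(values >= q75, 1, np.where(values >= q50, 2, np.where(values >= q25, 3, 4)))
    return CoreAssignment(
        cores=pd.Series(cores, index=pd.Index(nodes, name="node_id"), name="core"),
        cut_points=(q25, q50, q75),
    )


def core_attribute_table(
    assignment: CoreAssignment,
    roster: Mapping[str, Professional],
    attribute: str = "location",
) -> pd.DataFrame:
    """Contingency table core x category, with within-category percentages.

    Returns a frame indexed by core (1..4) with one count column and
    one ``pct_`` column per category; each pct column sums to 100 up to
    rounding.
    """
    cores = assignment.cores
    categories = pd.Series(
        [getattr(roster[n], attribute) for n in cores.index], index=cores.index
    )
    counts = pd.crosstab(cores, categories)
    counts = counts.reindex(index=[1, 2, 3, 4], fill_value=0)
    counts.index.name = "core"
    pct = 100.0 * counts / counts.sum(axis=0)
    pct.columns = [f"pct_{c}" for c in pct.columns]
    return pd.concat([counts, pct], axis=1)


def peeling_k_cores(graph: nx.DiGraph) -> pd.Series:
    """Classical iterative k-core (coreness) numbers, for reference only.

    Computed on the undirected projection; not used by the pipeline,
    whose hierarchy is the outdegree-quantile binning above.
    """
    coreness = nx.core_number(nx.Graph(graph))
    nodes = sorted(coreness)
    return pd.Series([coreness[n] for n in nodes], index=pd.Index(nodes, name="node_id"), name="coreness")
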