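"""Hierarchical clustering of professionals on their node metrics.

The six node metrics are z-scored (population SD) so each contributes
equally, then agglomeratively clustered (Ward linkage on Euclidean
distance by default).  The number of clusters is chosen by scanning
k = 2..10 and keeping the k with the highest mean silhouette score.
Cluster labels are renumbered by descending median outdegree, so
cluster 1 is always the best-connected group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .events import Professional

LINKAGES = ("ward", "complete", "average")


def standardize(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column to mean 0 and unit (population) variance.

    A constant column carries no clustering information and makes the
    z-score undefined, so it is reported as an error rather than
    silently dropped.
    """
    if len(metric_table) < 2:
        raise ValueError("standardize needs at least 2 rows")
    means = metric_table.mean(axis=0)
    stds = metric_table.std(axis=0, ddof=0)
    constant = stds[stds == 0.0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be standardized: {constant}")
    return (metric_table - means) / stds


def hierarchical_cluster(
    features: pd.DataFrame, k: int, linkage: str = "ward"
) -> np.ndarray:
    """Agglomerative clustering into k groups; returns raw labels (0..k-1).

    Euclidean distance throughout; deterministic for a given row order
    (scikit-learn breaks merge ties by pair index).
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > len(features):
        raise ValueError(f"k={k} exceeds number of rows {len(features)}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    model = AgglomerativeClustering(n_clusters=k, linkage=linkage, metric="euclidean")
    return model.fit_predict(features.to_numpy())


@dataclass
class ClusterAssignment:
    """Labels (1..k, 1 = best connected), chosen k, silhouette scan."""

    labels: pd.Series            # index node_id, values 1..k
    chosen_k: int
    silhouette_by_k: dict[int, float]
    linkage: str


def _relabel_by_outdegree(labels: np.ndarray, features: pd.DataFrame) -> np.ndarray:
    """Renumber labels so cluster 1 has the highest median outdegree.

    Falls back to descending cluster size when the feature table has no
    outdegree column; ties broken by the raw label for determinism.
    """
    raw = np.unique(labels)
    if "outdegree" in features.columns:
        order = sorted(
            raw,
            key=lambda c: (-float(np.median(features["outdegree"].to_numpy()[labels == c])), c),
        )
    else:
        order = sorted(raw, key=lambda c: (-(labels == c).sum(), c))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    return np.array([mapping[c] for c in labels])


def select_k(
    features: pd.DataFrame,
    k_range: Sequence[int] = range(2, 11),
    linkage: str = "ward",
) -> ClusterAssignment:
    """Scan k over ``k_range``, score each partition by mean silhouette,
    and keep the argmax (ties to the smaller k)."""
    if len(features) <= max(k_range):
        raise ValueError("need more rows than the largest k scanned")
    silhouettes: dict[int, float] = {}
    partitions: dict[int, np.ndarray] = {}
    x = features.to_numpy()
    for k in k_range:
        labels = hierarchical_cluster(features, k, linkage)
        partitions[k] = labels
        silhouettes[k] = float(silhouette_score(x, labels, metric="euclidean"))
    chosen_k = min(silhouettes, key=lambda k: (-silhouettes[k], k))
    final = _relabel_by_outdegree(partitions[chosen_k], features)
    return ClusterAssignment(
        labels=pd.Series(final, index=features.index, name="cluster"),
        chosen_k=chosen_k,
        silhouette_by_k=silhouettes,
        linkage=linkage,
    )


def _median_iqr(values: pd.Series) -> tuple[float, float, float]:
    clean = values.dropna()
    if clean.empty:
        return (np.nan, np.nan, np.nan)
    return (
        float(clean.median()),
        float(clean.quantile(0.25)),
        float(clean.quantile(0.75)),
    )


def profile_clusters(
    labels: pd.Series,
    metric_table: pd.DataFrame,
    roster: Mapping[str, Professional],
    behaviors: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-cluster summary: size, inpatient share, role mix, and
    median (q1, q3) of every metric and behavior column.

    One row per cluster, mirroring how cluster subgroups are reported:
    n, location share, role composition percentages, then
    ``<column>_median`` / ``_q1`` / ``_q3`` triples.
    """
    table = metric_table.copy()
    if behaviors is not None:
        table = table.join(behaviors, how="left")
    rows = []
    n_total = len(labels)
    for cluster in sorted(labels.unique()):
        ids = labels.index[labels == cluster]
        row: dict = {"cluster": int(cluster), "n": len(ids)}
        row["pct_of_total"] = 100.0 * len(ids) / n_total
        locs = [roster[i].location for i in ids if i in roster]
        row["n_inpatient"] = sum(1 for l in locs if l == "inpatient")
        row["pct_inpatient"] = 100.0 * row["n_inpatient"] / len(locs) if locs else np.nan
        roles = pd.Series([roster[i].role for i in ids if i in roster])
        for role, share in (100.0 * roles.value_counts(normalize=True)).items():
            row[f"role_pct_{role}"] = float(share)
        for column in table.columns:
            med, q1, q3 = _median_iqr(table.loc[table.index.isin(ids), column])
            row[f"{column}_median"] = med
            row[f"{column}_q1"] = q1
            row[f"{column}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster").sort_index()
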