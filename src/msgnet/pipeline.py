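"""End-to-end orchestration: simulate/load -> build -> metrics -> cores
-> clusters -> behaviors -> comparisons -> report.

Every stage writes its artifact under the run directory and appends a
row-count entry to the manifest; a rerun with the same config and seed
is bit-identical.  Stochastic stages draw their own seed derived from
the master seed, so any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .behaviors import behavior_table
from .cluster import profile_clusters, select_k, standardize
from .cores import assign_cores, compute_cut_points, core_attribute_table
from .events import (
    CleanedEvents,
    categorize_roles,
    clean_events,
    read_event_log,
    write_event_log,
)
from .global_metrics import global_metric_report
from .graph import (
    build_network,
    gcc_coverage,
    giant_connected_component,
    write_edgelist_csv,
    write_graphml,
)
from .metrics import DistanceConvention, node_metric_table
from .stats import (
    bootstrap_median_diff_ci,
    chi_square,
    kruskal_wallis,
    mann_whitney,
    pairwise_wilcoxon_bonferroni,
    results_table,
)
from .synth import DEFAULT_ROLE_MAP, SimConfig, plant_metric_clusters, simulate_event_log, simulate_roster, write_ground_truth

log = logging.getLogger("msgnet")

STAGES = (
    "events",
    "network",
    "node_metrics",
    "global_metrics",
    "cores",
    "clusters",
    "behaviors",
    "comparisons",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str = "msgnet_run"
    seed: int = 0
    input_path: Optional[str] = None       # read this log instead of simulating
    role_map_path: Optional[str] = None    # raw-role -> category CSV (real logs)
    sim: SimConfig = field(default_factory=SimConfig)
    planted: bool = False                  # plant latent metric clusters
    planted_n: int = 2000
    centrality_convention: str = DistanceConvention.INVERSE_WEIGHT.value
    diameter_convention: str = DistanceConvention.DIRECT_WEIGHT.value
    eigenvector_direction: str = "incoming"
    linkage: str = "ward"
    k_min: int = 2
    k_max: int = 10
    volume_denominator: str = "active_days"
    n_boot: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        config = cls(**raw)
        if sim_raw:
            config.sim = SimConfig(**{
                k: v for k, v in sim_raw.items()
            })
        return config

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 100_003 + STAGES.index(stage) + 1) % (2**31)


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    A stage failure propagates after the preceding artifacts were
    already written, so partial runs remain inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "msgnet_version": __version__,
        "seed": config.seed,
        # out_dir is echoed nowhere: the manifest describes the run, not
        # where it lives, so reruns in different directories stay identical
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "out_dir"
        },
        "stages": {},
    }

    # --- stage 1: obtain events -------------------------------------------
    truth = None
    if config.input_path:
        parsed = read_event_log(config.input_path)
        events = parsed.events
        n_rejected = parsed.n_rejected
        if config.role_map_path:
            from .events import read_role_map

            role_map = read_role_map(config.role_map_path)
        else:
            role_map = dict(DEFAULT_ROLE_MAP)
    else:
        sim = dataclasses.replace(config.sim, seed=config.stage_seed("events"))
        if config.planted:
            planted = plant_metric_clusters(n=config.planted_n, seed=sim.seed, base=sim)
            roster_sim, events = planted.roster, planted.events
            truth = planted
            write_ground_truth(out / "ground_truth.json", planted, sim.seed)
        else:
            roster_sim = simulate_roster(sim)
            events = simulate_event_log(sim, roster_sim)
        write_event_log(events, out / "events.csv")
        n_rejected = 0
        role_map = dict(DEFAULT_ROLE_MAP)
    roster = categorize_roles(events, role_map)
    cleaned: CleanedEvents = clean_events(events)
    manifest["stages"]["events"] = {
        "n_events": len(events),
        "n_rejected": n_rejected,
        "n_professionals": len(roster),
        "n_for_weighting": len(cleaned.for_weighting),
    }
    log.info("events: %d messages, %d professionals", len(events), len(roster))

    # --- stage 2: network --------------------------------------------------
    graph = build_network(cleaned.for_weighting, roster)
    gcc = giant_connected_component(graph)
    write_graphml(gcc, out / "gcc.graphml")
    write_edgelist_csv(gcc, out / "gcc_edges.csv")
    node_pct, edge_pct = gcc_coverage(
        graph.number_of_nodes(), graph.number_of_edges(),
        gcc.number_of_nodes(), gcc.number_of_edges(),
    )
    manifest["stages"]["network"] = {
        "total_nodes": graph.number_of_nodes(),
        "total_edges": graph.number_of_edges(),
        "gcc_nodes": gcc.number_of_nodes(),
        "gcc_edges": gcc.number_of_edges(),
        "gcc_node_pct": node_pct,
        "gcc_edge_pct": edge_pct,
    }
    log.info("network: GCC %d nodes (%.1f%%), %d edges (%.1f%%)",
             gcc.number_of_nodes(), node_pct, gcc.number_of_edges(), edge_pct)

    # --- stage 3: node metrics --------------------------------------------
    convention = DistanceConvention(config.centrality_convention)
    metrics = node_metric_table(gcc, convention, config.eigenvector_direction)
    annotated = metrics.copy()
    annotated.insert(0, "role", [roster[n].role if n in roster else "" for n in metrics.index])
    annotated.insert(1, "location", [roster[n].location if n in roster else "" for n in metrics.index])
    annotated.to_csv(out / "node_metrics.csv")
    manifest["stages"]["node_metrics"] = {"n_nodes": len(metrics)}

    # --- stage 4: global metrics ------------------------------------------
    attrs = {
        "location": {n: roster[n].location for n in gcc.nodes if n in roster},
        "role": {n: roster[n].role for n in gcc.nodes if n in roster},
    }
    report = global_metric_report(gcc, attrs, DistanceConvention(config.diameter_convention))
    _dump_json(report, out / "global_metrics.json")
    manifest["stages"]["global_metrics"] = {"n_metrics": 5}

    # --- stage 5: cores ----------------------------------------------------
    outdeg = metrics["outdegree"].to_dict()
    cuts = compute_cut_points(list(outdeg.values()))
    assignment = assign_cores(outdeg, cuts)
    core_frame = pd.DataFrame({
        "outdegree": pd.Series(outdeg),
        "core": assignment.cores,
    })
    core_frame.index.name = "node_id"
    core_frame.to_csv(out / "cores.csv")
    _dump_json({"cut_points": {"q25": cuts[0], "q50": cuts[1], "q75": cuts[2]}},
               out / "core_cut_points.json")
    core_loc = core_attribute_table(assignment, roster, "location")
    core_loc.to_csv(out / "core_by_location.csv")
    core_role = core_attribute_table(assignment, roster, "role")
    core_role.to_csv(out / "core_by_role.csv")
    manifest["stages"]["cores"] = {
        "cut_points": list(cuts),
        "core_sizes": assignment.cores.value_counts().sort_index().to_dict(),
    }

    # --- stage 6: clusters -------------------------------------------------
    features = standardize(metrics)
    clusters = select_k(features, range(config.k_min, config.k_max + 1), config.linkage)
    clusters.labels.to_csv(out / "clusters.csv")
    _dump_json(
        {
            "chosen_k": clusters.chosen_k,
            "linkage": clusters.linkage,
            "silhouette_by_k": {str(k): v for k, v in clusters.silhouette_by_k.items()},
        },
        out / "silhouette.json",
    )
    manifest["stages"]["clusters"] = {
        "chosen_k": clusters.chosen_k,
        "cluster_sizes": clusters.labels.value_counts().sort_index().to_dict(),
    }
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        common = [n for n in clusters.labels.index if n in truth.labels]
        ari = adjusted_rand_score(
            [truth.labels[n] for n in common],
            [int(clusters.labels[n]) for n in common],
        )
        manifest["stages"]["clusters"]["adjusted_rand_vs_truth"] = float(ari)

    # --- stage 7: behaviors ------------------------------------------------
    window_days = (config.sim.window_end - config.sim.window_start).days + 1
    behaviors = behavior_table(
        cleaned.for_counts,
        denominator=config.volume_denominator,
        window_days=window_days,
    )
    behaviors.to_csv(out / "behaviors.csv")
    profiles = profile_clusters(clusters.labels, metrics, roster, behaviors)
    profiles.to_csv(out / "cluster_profiles.csv")
    manifest["stages"]["behaviors"] = {"n_professionals": len(behaviors)}

    # --- stage 8: comparisons ----------------------------------------------
    results = []
    by_location = {
        loc: metrics.index[[roster[n].location == loc for n in metrics.index]]
        for loc in ("inpatient", "outpatient")
    }
    boot_seed = config.stage_seed("comparisons")
    for column in metrics.columns:
        a = metrics.loc[by_location["inpatient"], column]
        b = metrics.loc[by_location["outpatient"], column]
        if len(a) and len(b):
            res = mann_whitney(a, b, names=("inpatient", "outpatient"))
            boot = bootstrap_median_diff_ci(a, b, config.n_boot, boot_seed, ("inpatient", "outpatient"))
            res.median_difference = boot.median_difference
            res.ci_low, res.ci_high = boot.ci_low, boot.ci_high
            res.seed, res.n_boot = boot.seed, boot.n_boot
            res.test = f"mann_whitney[{column}]"
            results.append(res)
    roles_present = sorted({roster[n].role for n in metrics.index if n in roster})
    if len(roles_present) >= 3:
        for column in metrics.columns:
            groups = [
                metrics.loc[[n for n in metrics.index if roster[n].role == role], column]
                for role in roles_present
            ]
            keep = [(g, r) for g, r in zip(groups, roles_present) if len(g)]
            res = kruskal_wallis([g for g, _ in keep], tuple(r for _, r in keep))
            res.test = f"kruskal_wallis_role[{column}]"
            results.append(res)
    for name, table in (("location", core_loc), ("role", core_role)):
        counts = table[[c for c in table.columns if not str(c).startswith("pct_")]]
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        counts = counts.loc[counts.sum(axis=1) > 0]
        if counts.shape[0] >= 2 and counts.shape[1] >= 2:
            res = chi_square(counts.to_numpy())
            res.test = f"chi_square_core_x_{name}"
            results.append(res)
    cluster_ids = sorted(clusters.labels.unique())
    for column in behaviors.columns:
        groups = [
            behaviors.loc[behaviors.index.intersection(clusters.labels.index[clusters.labels == c]), column].dropna()
            for c in cluster_ids
        ]
        named = [(g, c) for g, c in zip(groups, cluster_ids) if len(g) >= 2]
        if len(named) >= 3:
            res = kruskal_wallis([g for g, _ in named], tuple(c for _, c in named))
            res.test = f"kruskal_wallis_cluster[{column}]"
            results.append(res)
        if len(named) >= 2:
            pairwise = pairwise_wilcoxon_bonferroni(
                [g for g, _ in named], [str(c) for _, c in named]
            )
            for res in pairwise:
                res.test = f"wilcoxon_cluster[{column}]"
            results.extend(pairwise)
    results_table(results).to_csv(out / "comparisons.csv", index=False)
    manifest["stages"]["comparisons"] = {"n_tests": len(results)}

    _dump_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt_median_iqr(series: pd.Series) -> str:
    clean = series.dropna()
    if clean.empty:
        return "-"
    return f"{clean.median():.3g} ({clean.quantile(0.25):.3g} to {clean.quantile(0.75):.3g})"


def render_report(out_dir, p_threshold: float = 0.001) -> str:
    """Human-readable summary of a finished run.

    Emits a node-metric table stratified by location and role
    (median (IQR) per metric) and a cluster-profile table with
    pairwise-significance letters: behavior rows get letter ``a``
    (``b``, ``c``) when the Bonferroni-adjusted p against cluster 1
    (2, 3) falls below ``p_threshold``.
    """
    out = Path(out_dir)
    metrics = pd.read_csv(out / "node_metrics.csv", index_col=0)
    behaviors = pd.read_csv(out / "behaviors.csv", index_col=0)
    clusters = pd.read_csv(out / "clusters.csv", index_col=0)["cluster"]
    comparisons = pd.read_csv(out / "comparisons.csv")

    metric_cols = [c for c in metrics.columns if c not in ("role", "location")]
    lines = ["== Node metrics by location and clinical role (median (IQR)) =="]
    header = "stratum".ljust(34) + "  ".join(c.ljust(22) for c in metric_cols)
    lines.append(header)
    for attr in ("location", "role"):
        for value, block in metrics.groupby(attr):
            row = str(value).ljust(34)
            row += "  ".join(_fmt_median_iqr(block[c]).ljust(22) for c in metric_cols)
            lines.append(row)

    lines.append("")
    lines.append("== Cluster profiles (median (IQR); letters mark adjusted "
                 f"P<{p_threshold} vs clusters 1-3) ==")
    joined = behaviors.join(clusters, how="inner")
    cluster_ids = sorted(joined["cluster"].unique())
    lines.append("measure".ljust(26) + "  ".join(f"cluster {c}".ljust(30) for c in cluster_ids))
    sizes = joined.groupby("cluster").size()
    lines.append("n".ljust(26) + "  ".join(str(sizes.get(c, 0)).ljust(30) for c in cluster_ids))
    letters = "abcdefghij"
    for column in behaviors.columns:
        pair = comparisons[comparisons["test"] == f"wilcoxon_cluster[{column}]"]
        cells = []
        for c in cluster_ids:
            text = _fmt_median_iqr(joined.loc[joined["cluster"] == c, column])
            marks = ""
            for other in cluster_ids:
                if other >= c:
                    continue
                hit = pair[
                    (pair["groups"].isin([f"{other}|{c}", f"{c}|{other}"]))
                    & (pair["adjusted_p"] < p_threshold)
                ]
                if len(hit):
                    marks += letters[int(other) - 1]
            cells.append((text + (f" [{marks}]" if marks else "")).ljust(30))
        lines.append(str(column).ljust(26) + "  ".join(cells))
    return "\n".join(lines) + "\n"
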