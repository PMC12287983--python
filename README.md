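# msgnet

Social network analysis of clinical secure-messaging event logs.

Hospital teams increasingly coordinate through asynchronous secure
messages inside the electronic health record. Each message — sender,
receiver, conversation thread, timestamps, character length — is one
row of an event log, and six months of such logs define a large
directed communication network whose structure shapes (and reflects)
how clinicians work. `msgnet` turns a dyadic message event log into
that network and characterizes it end to end, for health-informatics
researchers studying communication load and for anyone who needs a
reproducible reference implementation of this style of analysis.

## What it computes

Starting from events (one row per message), the pipeline:

1. **builds the network** — a node per professional, a directed edge
   u→v when u sent at least one nonempty message to v (so at most two
   edges per pair), edge weight w(u→v) = Σ characters sent, and keeps
   the giant weakly connected component (GCC);
2. **node metrics** — indegree and outdegree (unweighted partner
   counts), closeness centrality C(x) = (|R_x|−1)/Σ_{y∈R_x} d(y,x)
   with inverse-weight distances d using 1/w per edge (heavier
   communication = closer), weighted eigenvector centrality
   x_i ∝ Σ_j w_ji x_j, unnormalized directed betweenness
   Σ_{s≠t≠v} σ_st(v)/σ_st on inverse-weight shortest paths, and the
   local clustering coefficient on the undirected projection;
3. **global metrics** — density E/(N(N−1)), reciprocity, weighted
   diameter, transitivity, and Newman assortativity
   r = (Σᵢeᵢᵢ − Σᵢaᵢbᵢ)/(1 − Σᵢaᵢbᵢ) by practice location, role, and
   total degree;
4. **core hierarchy** — nodes binned into four cores by the 25th/50th/
   75th percentiles (nearest-rank) of GCC outdegree, core 1 = top
   quartile;
5. **clusters** — the six node metrics z-scored, Ward agglomerative
   clustering, the number of clusters chosen by the mean silhouette
   score over k = 2..10, labels renumbered so cluster 1 is the
   best-connected group;
6. **behaviors** — per professional: mean message read time and
   conversation response time (minutes), daily message volume, and
   mean characters per message sent and received;
7. **comparisons** — Mann-Whitney U (location), Kruskal-Wallis (roles,
   clusters), chi-square (core × attribute), pairwise Wilcoxon
   rank-sum with Bonferroni adjustment, and percentile-bootstrap 95%
   CIs for median differences.

Because real clinical logs cannot be shared, the package ships a
synthetic generator (`msgnet.synth`) that emulates the statistical
shape of such logs — heavy-tailed partner counts, location homophily,
log-normal lengths and delays, threaded conversations — and can plant
latent node groups with known labels so cluster recovery is testable.

## Worked example

```python
from msgnet import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(out_dir="demo_run", seed=42,
                sim=SimConfig(n_professionals=300))
manifest = run_pipeline(cfg)
print(manifest["stages"]["network"])
print(manifest["stages"]["clusters"])
```

prints

```
{'total_nodes': 300, 'total_edges': 10278, 'gcc_nodes': 300,
 'gcc_edges': 10278, 'gcc_node_pct': 100.0, 'gcc_edge_pct': 100.0}
{'chosen_k': 4, 'cluster_sizes': {1: 1, 2: 75, 3: 165, 4: 59}}
```

i.e. the simulated 300-professional log yields a fully connected
10,278-edge digraph, and silhouette-guided Ward clustering of the
z-scored node metrics picks four groups — cluster 1 here is a single
extreme hub (the generator's hub multiplier at small n), clusters 2–4
are the broad connectivity tiers. `demo_run/global_metrics.json` holds
the network-level summary:

```
"density": 0.1146, "reciprocity": 0.8918, "transitivity": 0.5874,
"assortativity": {"location": 0.218, "role": -0.013, "total_degree": -0.462}
```

Reciprocity ≈ 0.89 reflects that most simulated conversations are
answered; density and transitivity are far higher than in a real
30,000-node system simply because the toy network is 100× smaller.
All artifacts (GraphML graph, per-node metric/core/cluster/behavior
CSVs, comparison tables, a run manifest) land in `demo_run/`; rerunning
with the same config and seed reproduces them bit for bit. The same
pipeline is scriptable from the shell:

```bash
msgnet run-all --seed 42 --out demo_run
msgnet report demo_run        # median (IQR) tables by location/role/cluster
```

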