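# Methods

This note records the modeling conventions, defaults, and numerical
choices behind `msgnet`, and what the synthetic validation does and
does not establish.

## Event model and cleaning

A message event is dyadic (sender ≠ receiver), timestamped at second
resolution in a single declared timezone-naive clock, and carries a
character count that includes internal spaces but not trailing
whitespace. Cleaning drops exact duplicate rows and sorts by
(sent time, conversation, sender, receiver), so the cleaned stream is
invariant to input order. Zero-length messages are excluded from edge
weighting — an edge of weight 0 has no inverse-weight distance — but
retained for the volume behaviors, where an empty message is still a
message handled. Each professional's role is their most recent raw
role observed (as sender or receiver) mapped through a raw→category
table with eight categories (physician, nurse, pharmacist, advanced
practice provider, therapist, medical assistant/technician, social
work/case management, other); unmapped raw roles fall back to *other*
with a warning. Location is the majority of observed practice
locations; ties resolve to inpatient (configurable), a deterministic
choice consistent with an inpatient-heavy cohort.

## Network construction

Every message endpoint becomes a node. The source material defines
membership by having *sent* a message, which would leave
receive-only professionals as edge endpoints without node status — a
contradiction; including all endpoints and then restricting every
analysis to the giant weakly connected component resolves it, since
the GCC step discards exactly the disconnected remnant either way.
Edge weight is the summed character length sender→receiver;
`message_count` rides along as metadata. GCC ties (equal component
sizes) break toward the component containing the smallest node id.

## Metric conventions

* **Degrees** count distinct partners (unweighted edges). Indegree is
  the number of professionals who message you; outdegree the number
  you message.
* **Distances** for closeness and betweenness use inverse weights:
  an edge of weight w contributes 1/w, so a heavily used channel is a
  short hop. The implementation delegates Dijkstra and Brandes-style
  path counting to igraph's C core; brute-force Floyd-Warshall and
  exhaustive path-enumeration oracles in the test suite pin down the
  semantics.
* **Closeness** is incoming by default — (|R|−1)/Σ_{y∈R} d(y,x) over
  the set R of nodes that can reach x. The reachable-set form keeps
  the statistic defined on weakly connected digraphs, where a global
  (N−1) numerator would be undefined; an outgoing variant is a flag.
* **Eigenvector centrality** uses the weighted adjacency, incoming
  direction by default (influence accrues from being messaged by
  central nodes); power iteration from the uniform positive vector,
  unit-L2 output, convergence when the L2 step change falls below
  1e-10, hard cap 10,000 iterations (exceeding it raises). On a
  nilpotent adjacency (a DAG) the centrality mass vanishes and an
  all-zero vector is returned. The quantity is only well defined when
  the dominant eigenvalue is simple; the random-digraph validation
  suite conditions its samples on a clear spectral gap for exactly
  this reason.
* **Betweenness** is directed and unnormalized: reported magnitudes
  are raw shortest-path counts, the scale on which hub brokerage is
  meaningful in a large network. Tied path lengths are compared at
  igraph's internal tolerance; the enumeration oracle uses a 1e-9
  relative tolerance, and test weights are drawn from 1..10 so that
  genuinely different inverse-weight path sums differ by far more.
* **Clustering coefficient and transitivity** are computed on the
  undirected, unweighted projection — no directed variant is implied
  by the definitions being reimplemented, and the undirected reading
  is the simplest consistent one.
* **Diameter** defaults to direct edge-weight sums (the stated
  "sum of the edge weight" reading) even though node centralities use
  inverse weights; both conventions are available and the choice is
  recorded in every run manifest. No attempt is made to reproduce any
  particular published diameter value, whose weighting convention is
  not recoverable.
* **Assortativity**: categorical attributes use Newman's mixing-matrix
  r on directed unweighted edges (r = 1 exactly when the trace of the
  mixing matrix is 1); degree assortativity is the Pearson correlation
  of total degree (in+out) across directed edges and is undefined
  (raises) at zero variance, e.g. on regular graphs.

## Core hierarchy

The hierarchy is quantile *binning*, not iterative k-core peeling: the
25th/50th/75th percentiles of GCC outdegree split nodes into cores
4..1, with "at or above" binding to the highest qualifying core, so
degenerate cut points collapse lower cores to empty rather than
erroring. Quantiles are nearest-rank (type 1), so every cut point is
an outdegree that actually occurs; interpolating methods are available
by flag. A classical peeling coreness is provided for reference but is
not part of the pipeline.

## Clustering

Features are the six node metrics, z-scored with population SD;
a constant column is a hard error (it carries no information and makes
the z-score undefined). Agglomerative clustering uses Euclidean
distance with Ward linkage by default — variance-minimizing linkage is
the standard choice for z-scored features; complete and average
linkage are flags. k is scanned over 2..10 and chosen by the mean
silhouette score, ties to the smaller k. Labels are renumbered by
descending median outdegree so cluster 1 is always the best-connected
group. Silhouette is computed on all rows at the scales used here
(≤ a few thousand nodes); a seeded subsample flag exists for larger
runs.

## Behaviors

Read time averages (read − sent) over a receiver's *read* messages;
unread messages are excluded rather than imputed. Response time is one
interval per conversation — first message by the initiator to first
message by the other party — attributed to the responder (it measures
their responsiveness; dyad attribution is a flag), implementing a
strict first-vs-first reading regardless of interleaved
self-continuations. Daily volume divides (sent + received) by active
days (distinct dates with any traffic) by default, which is robust to
enrollment gaps; a calendar-window denominator is a flag. Character
profiles are plain means per direction. Professionals with no
qualifying events get missing values, never zeros.

## Statistics

All tests are two-sided: Mann-Whitney U (exact for small tie-free
samples, tie-corrected normal approximation otherwise),
Kruskal-Wallis with the chi-square reference on k−1 df, Pearson
chi-square without continuity correction, and pairwise Wilcoxon
rank-sum post hocs with a Bonferroni multiplier equal to the k(k−1)/2
comparisons within one measure's family. CIs for median differences
are 95% percentile bootstrap with independent resampling of both
groups, 1000 resamples by default (the resample count is a package
choice; it is recorded with the seed in every result row).

## Synthetic generator

The generator emulates the statistical shape of a health-system
messaging log; its defaults are the package's study conditions.
Partner counts follow a truncated discrete power law P(k) ∝ k^-α with
α = 1 and cap 300, giving a median near 15 partners with a long tail;
a handful of hubs get a 5× partner multiplier. Dyads form by
configuration-model-style matching with a homophily step: a dyad joins
same-location professionals with probability `location_homophily`
(default 0.8), opposite-location otherwise, with a hard constraint (no
fallback) at the limits 0 and 1 so that homophily 1 yields location
assortativity exactly 1. On an imbalanced roster the *realized*
assortativity sits below the dyad-level homophily (≈0.3 at the
defaults with 71% inpatient) because the minority location exhausts
its same-location partner pool. Message lengths and read/response
delays are log-normal (medians ≈60 characters, 20 and 25 minutes —
the scales reported for clinical secure messaging); conversations are
threaded, answered with probability 0.7, and continue geometrically.
A roster default of 500 professionals keeps a full pipeline run under
half a minute on one CPU.

The planted-structure variant wires four latent tiers — hubs (2% of
nodes, ≈120 partners), connectors (20%, ≈40), peripherals (60%, ≈6),
and a cliquey tier (18%) sewn into closed 6-cliques with one outside
link per member, pinning its clustering coefficient near 2/3 — so the
groups occupy distinct regions of metric space (degree tiers are
geometrically spaced; the cliquey tier separates on clustering and
closeness rather than degree). Validation shows silhouette-guided Ward
clustering recovers k = 4 with adjusted Rand ≥ 0.99 across seeds at
n = 2000.

**What passing these tests does not show.** The generator produces
clean dyadic threads with stationary rates; real logs have shift
structure, bursts, group threads filtered upstream, role-dependent
messaging styles, and location assignment noise. Small synthetic
networks are far denser than a 30,000-node system, so their
transitivity and density are not comparable to production values;
only the arithmetic identities on published counts (GCC coverage
percentages, density) carry over exactly. Cluster recovery on planted
tiers demonstrates the machinery, not that four clusters exist in any
particular health system.

## Validation sizes and numerics

Oracle suites run 200 seeded random digraphs of ≤6 nodes (exhaustive
Floyd-Warshall, path enumeration, dense eigensolvers, neighbor-pair
enumeration), 100 random degree sequences for the core invariants,
2000 null replicates for test calibration at α = 0.05, and 500 shift
simulations for bootstrap coverage with 151 observations per group —
an odd, moderately large size at which the sample median's lattice
effects on percentile-CI coverage are mild. The planted-recovery
experiment uses 2000 nodes. These sizes were chosen as the smallest
at which each property is sharply testable; a full suite runs in
about half a minute.
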