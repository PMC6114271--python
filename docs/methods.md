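# Methods

## Scope and model

`herbnet` implements the inference chain used in network-pharmacology
studies of multi-herb formulas: ADME-based compound screening, bipartite
compound–target (CT) network construction, protein–protein interaction
(PPI) topology with median-based hub detection, drug/disease gene-set
intersection, and gene-set over-representation analysis.  The package
consumes database-style exports (compound property tables, edge lists,
gene lists, GMT annotation snapshots); it does not query databases, train
QSAR bioavailability models, predict compound targets, or compute
molecular descriptors from structures — those upstream products enter as
inputs.

## Drug-likeness and the ADME screen

Drug-likeness of a compound with descriptor vector A against a reference
profile B is the Tanimoto similarity

    f(A, B) = A·B / (|A|² + |B|² − A·B).

For non-negative vectors the value lies in [0, 1], is symmetric, equals
1 exactly for identical non-zero vectors, and reduces to the Jaccard
index on binary vectors.  Two readings of "similarity to a reference
bank" exist; the default scores against the **centroid** (mean
descriptor vector) of the bank, because the formula takes a single B.
Averaging per-molecule similarities instead is available via
`method="mean_similarity"`.  Similarity of two all-zero vectors is an
*error*, not 0: an all-zero descriptor vector almost always means an
upstream descriptor-computation failure, and silently scoring it would
hide that.

The screen keeps compounds with OB ≥ 30 % **and** DL ≥ 0.18, both
inclusive.  Rejections are annotated `low_ob`, `low_dl` or `both`.
Filtering partitions its input exactly and is idempotent.

## Networks

All graphs are undirected and unweighted (`networkx.Graph`); no
interaction directions, weights or confidence thresholds are modeled.
CT networks are bipartite with a `partition` node attribute; a name
appearing as both compound and target is rejected rather than merged
(compound ids follow a `C##` convention, gene symbols are upper-cased,
so the namespaces stay disjoint).  CT edges are unweighted; nothing in
the consumed exports carries a defensible weight.

The drug/disease intersection is a **node-set** intersection of the two
gene namespaces — compound nodes excluded — with the merged graph
keeping all edges from both sources and per-node provenance
(drug-only / disease-only / shared).  An empty intersection is a valid,
loudly logged result.

## Topology and the hub rule

Degree is the incident-edge count.  Betweenness is standard
shortest-path betweenness, unnormalized by default (the value is the
number of unordered node pairs routed through the node, fractional under
ties); a normalized variant is available.  Radius and diameter are the
extremes of per-node eccentricity under unweighted BFS; the
characteristic path length is the mean shortest-path length over
connected unordered pairs.  Disconnected graphs are reduced to their
largest connected component with a warning; a singleton graph has radius
= diameter = 0 and an undefined (null) path length; an empty graph is an
error.

Hubs are nodes whose degree is **strictly greater than twice the
median** degree of their scope; ties at the threshold are excluded, and
an even-count median is the mean of the two middle values.  On bipartite
CT networks the scope defaults to the partition: compound and target
degree distributions differ by an order of magnitude, and a pooled
median would let the larger partition's degrees set the threshold for
both.  On the packaged 70-compound table the compound-degree median is 9,
the threshold 18, and exactly 13 compounds exceed it.  Monopartite PPI
graphs use the whole node set.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for k query∩term genes, term size K, query size n, background
N, computed through `scipy.stats.hypergeom` (log-gamma arithmetic).
One-sided testing is the default since over-representation is the use
case; a two-sided option doubles the smaller tail.  Multiple testing is
controlled with Benjamini–Hochberg at FDR 0.05 across the tested terms
(after a term-size window of 3 ≤ K ≤ 500, both configurable).  Query
genes outside the background are dropped with a warning.

Redundant terms are grouped by Cohen's kappa on the 2×2 gene-membership
table over the background, κ = (Po − Pe)/(1 − Pe); a degenerate table
with Pe = 1 is defined as κ = 0 with a warning.  Significant terms with
pairwise κ ≥ 0.4 are merged by single-linkage connected components —
chosen over iterative leader heuristics for determinism — and each group
is labeled by its smallest-p member.

## Synthetic data

The generators emulate the *structure* of the database exports the
pipeline consumes, with ground truth planted by construction:

- **Compound tables** — OB log-normal (µ = 3.8, σ = 0.45 on the log
  scale, median ≈ 45 %), DL Beta(1.6, 3.0); both straddle the screening
  cut-offs.  A configured fraction of compounds (default 70/981, the
  scale of the study the package was built around) is drawn truncated
  above both thresholds, the rest forced below at least one, so the
  screen's outcome is exact, not approximate.
- **CT degrees** — truncated discrete power law (exponent 1.8, lower cut
  4, cap 160), matching the observed skew of real compound tables
  (median ≈ 9, maximum ≈ 150).  `degree_matched_ct_pairs` can also
  rebuild a pair list reproducing a published degree column exactly,
  with every target used when capacity allows and power-law target
  popularity for the remainder.
- **PPI graphs** — preferential attachment (default 15 edges per node,
  giving edge densities comparable to STRING/STITCH-style exports at
  n ≈ 250), with planted hubs boosted to ≥ 4× the median degree — safely
  above the 2×-median selection threshold — re-checking the median after
  boosting.  In small dense graphs the boost saturates at n − 1
  neighbors.
- **Overlap** — exactly `planted_overlap` genes are shared between the
  target and disease namespaces by explicit shared draws (no rejection
  sampling), so overlap counts are guaranteed.
- **Annotation** — decoy terms are uniform draws from a 2000-gene
  background; planted terms draw each member from the overlap genes
  (pipeline scenario) or the query draws from the planted term
  (standalone enrichment scenario) with probability 0.8.

All randomness flows through a single `numpy.random.Generator`; the same
seed yields byte-identical bundles.  What the generators do **not**
emulate: descriptor chemistry, GO DAG structure and term nesting,
annotation bias, correlated degree structure between the CT and PPI
layers, and gene-symbol aliasing.  Passing tests therefore demonstrate
correctness of the algorithms and recoverability of planted signal at
realistic scales — not robustness to the pathologies of real curated
annotations.

## Numerical and design choices

- Medians via `statistics.median`; hub ordering by (degree desc, name)
  for determinism.
- BH adjustment delegates to `statsmodels.stats.multitest`; p-values are
  validated to (0, 1].
- Enrichment rows sort by (p, term_id); kappa grouping orders groups by
  their representative's p-value.
- Problem sizes in the test-suite property checks (500 oracle graphs at
  n ≤ 8, full hypergeometric lattice at N ≤ 12, 200 enrichment
  replicates, 100 hub replicates) were chosen to make the checks
  exhaustive where enumeration is cheap and statistically decisive where
  it is not.
- Readers reject malformed numeric fields with line numbers instead of
  coercing; duplicate compound ids and duplicate GMT term ids are
  errors; empty GMT terms are skipped with a warning.

## Known limitations

- Published whole-study statistics that depend on unpublished database
  exports (e.g. exact PPI node/edge counts or a specific gene's degree)
  cannot be reproduced from the packaged table alone; the pipeline
  reproduces the published *rules* and validates the statistical
  machinery on synthetic data instead.
- Betweenness is reported but no centrality other than degree enters the
  hub rule.
- No UniProt/ID-mapping service; symbol harmonization is upper-casing
  only.
- The per-partition hub median is computed over nodes present in the
  graph; isolated proteins enter only if listed in an explicit node
  file.
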