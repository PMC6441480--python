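# Methods

## Scope and model

critnet implements a topology-driven biomarker-screening procedure for
small two-group expression designs. The underlying model is deliberately
simple: gene expression is observed on the log2 scale with additive noise;
differential expression is a mean shift between groups; the interaction
network is an unweighted, undirected simple graph; and "importance" in the
network is captured by three classical centralities. The end product is a
small panel of *critical* genes — simultaneously hubs (degree outliers) and
central (top-ranked by betweenness and closeness) — subsequently annotated
by gene-set enrichment.

## Differential expression

Samples are median-centered per column (each sample's median log2 intensity
becomes 0), which removes array-level location shifts and is idempotent.
Five-number summaries (`boxplot_stats`) provide the standard visual
comparability check.

Genes are ranked by a two-sample t-test on log2 values. The default is the
pooled-variance (Student) test rather than Welch's unequal-variance form:
with 2–3 samples per group — the regime this design targets — Welch's
Satterthwaite approximation is noticeably conservative (its measured null
size at α = 0.05 is ≈ 0.035 with n = 3 per group under Gaussian noise of a
common scale), which both distorts calibration and degrades the ranking.
Under the homoscedastic noise model the pooled test is exact (measured null
size 0.0486 over 20 000 null genes, within Monte-Carlo error of 0.05).
Welch's form remains available via `rank_genes(..., equal_var=False)` for
data where per-group variances genuinely differ. Degenerate genes with zero
variance in both groups take p = 1 when the group means agree and p = 0
otherwise, avoiding 0/0 while preserving the obvious inference. Ties in p
are broken by |log2 FC| descending, then gene id, so ranks are a
deterministic permutation.

DEG selection keeps the `top_n = 250` best-ranked genes and then applies
strict fold-change thresholds (FC < 0.5 or FC > 2.0; a gene at exactly 2.0
is removed). Fold change uses group means on the log2 scale (geometric
means on the linear scale). An optional "characterized" gene list drops
unannotated identifiers before network construction.

## Network topology

Graphs are built with self-loops dropped and duplicate/reversed edges
collapsed. All downstream analysis runs on the main connected component
(ties on size broken toward the component containing the lexicographically
smallest node id). Betweenness centrality is computed by Brandes'
dependency-accumulation algorithm on unweighted shortest paths, written
in-package and verified in the test suite against explicit all-geodesic
enumeration and against networkx; it is normalized by (N−1)(N−2)/2.
Closeness is (N−1)/Σ d(v,·) — the reciprocal of the mean shortest-path
distance. Both conventions match Cytoscape's NetworkAnalyzer on a connected
component, which keeps the output table comparable with that widely used
tool. Closeness across disconnected graphs is undefined under this
convention, so `compute_centralities` requires connected input.

The degree distribution (node counts per degree k ≥ 1) is fitted as
count = a·k^b by ordinary least squares of log count on log k; natural logs
are used (the base affects neither b, the Pearson correlation, nor R²; a is
recovered via exp). Degree-0 nodes cannot enter the fit (log 0). With two
points, or with constant logged counts, the line interpolates the data
exactly and R² is reported as 1 by convention (the Pearson r of a constant
vector is otherwise undefined). Whether counts or relative frequencies are
plotted changes only a, not b, the correlation or R²; the package fits raw
counts.

## Node selection

Hubs are nodes with degree ≥ mean + c·SD, with c = 2 and the sample SD
(ddof = 1); the inclusive ≥ means that a degree-regular graph (SD = 0)
returns all nodes. Central nodes are the top ⌈f·N⌉ by betweenness and by
closeness separately, f = 0.05 (so a 257-node component yields exactly 13
per metric); ties are broken by degree descending then node id, making the
count exact and the selection reproducible. The two central sets combine by
intersection by default — the stricter reading, appropriate when the panel
should be small and unambiguous — with union available via
`central_mode="union"`. Critical nodes are hubs ∩ central.

## Enrichment

Each term overlapping the query gets the right-tailed hypergeometric
p-value P(X ≥ k) for overlap k, term size K, query size n and universe U,
evaluated through scipy's survival function (accurate far into the tail).
The universe is the annotation table's own gene universe (for GMT input,
the union of all term gene sets — the "annotated background" convention);
query genes outside it are dropped with a logged warning. Adjustment is
Holm's step-down across all tested terms, the step-down analogue of
Bonferroni used by standard enrichment browsers; rows with adjusted
p < α = 0.05 are reported. %G/T is 100·k/K rounded half-up to two decimals,
matching how such tables are conventionally printed.

Term redundancy is summarized by Cohen's kappa between the binary
gene-membership vectors of term pairs over the universe, with
κ = (p_o − p_e)/(1 − p_e) and κ = 1 by convention when p_e = 1. Terms are
linked when κ ≥ 0.4 and clusters are the connected components of that
graph, ids ordered by each cluster's most significant member. This is a
transparent approximation of the iterative group-merging some enrichment
tools perform; it reproduces the qualitative structure (e.g. on the
packaged curated table over its six-gene panel, the HIF-1 signaling row —
the only term containing GAPDH — separates while the remaining 33 terms
form one cluster) without the tools' order-dependent merging heuristics.

## Packaged curated table

The fixture ships 34 curated enrichment rows for the six-gene colon-cancer
panel, preserving the printed gene spellings (including the "APK3" variant,
normalized to MAPK3 for membership counting — the published per-gene term
counts only balance under that reading). Term sizes K are recovered from
the printed %G/T as the integer reproducing it under half-up rounding; a
test verifies the round trip for all 34 rows. Counting memberships from the
printed gene lists yields MAPK3 34, AKT1 32, SRC 22, TP53 17, GAPDH 1,
ALB 0; the accompanying published summary sentence states 21 for SRC, one
fewer than its own table contains — the package reports what the table
yields.

## Synthetic data

`generate_expression` draws per-gene baselines from N(8, 2) on the log2
scale (typical microarray intensity range) and adds i.i.d. N(0, σ) noise
per entry; planted genes receive an additive log2 shift in group B only, so
the noise-free fold change is exactly 2^effect. Defaults — 1000 genes,
3 + 3 samples, 50 planted genes, effect 3, σ = 0.5 — mirror the small-n
grade-comparison design the pipeline targets, with a signal strong enough
that the DEG step should recover nearly all planted genes (measured: ≥ 45
of 50 in the top-50 DEGs at every probe seed). `generate_scale_free_network`
grows a preferential-attachment graph from a seed clique (so the result is
connected; a 2-clique when m = 1, which yields a tree). `planted_hub_graph`
adds one node wired to 40% of a 300-node preferential-attachment graph — a
degree/centrality outlier the selection rules must recover.
`generate_annotations` draws term gene sets uniformly without replacement;
its universe is the full supplied gene set. Everything is a pure function
of its arguments including the seed.

What the generators do *not* emulate: probe-level artifacts, batch effects,
correlated co-expression modules, interaction confidence scores, or the
dependency structure of real annotation hierarchies. Passing tests
therefore certify the machinery (ranking calibration, selection arithmetic,
oracle-exact centralities and p-values), not biological validity on any
particular real dataset.

## Numerical and calibration notes

- Hypergeometric p-values match exhaustive draw enumeration to 1e-12 for
  every configuration with U ≤ 12 (tested), and Brandes betweenness matches
  geodesic enumeration to 1e-9 on random connected graphs up to 40 nodes.
- The right-tailed hypergeometric test is discrete: its exact size at
  α = 0.05 is ≈ 0.034–0.037 for realistic term sizes (50–200 of a
  1000-gene universe, 100-gene query). Null-calibration checks therefore
  compare the simulated rejection rate to that exact size (computed from
  the null pmf) and additionally confirm the test never exceeds the nominal
  rate — discreteness makes it conservative, never anti-conservative.
- Problem sizes in the test and acceptance runs (200 null matrices of 100
  genes; 500 null enrichment queries; 30 oracle graphs ≤ 40 nodes; 2000-node
  attachment graphs) were chosen as the smallest sizes at which the
  Monte-Carlo bands (3·SE) are tight enough to detect miscalibration of a
  percentage point or less.

## Known limitations

- The enrichment clustering is single-linkage on a thresholded kappa graph;
  tools that iteratively merge overlapping groups can split or join
  borderline clusters differently.
- Closeness is undefined across components by design; analyses of
  disconnected networks must go through `main_component` (isolated-node
  counts are still reported).
- The pipeline treats interaction edges as unweighted and undirected;
  confidence scores and edge direction are out of scope, as is any live
  database retrieval — networks and annotations are file inputs.
- With 2–3 samples per group no ranking statistic is powerful in absolute
  terms; the calibration results say the p-values are honest, not that the
  design is well powered.
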