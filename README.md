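# critnet

Critical-gene discovery in protein–protein interaction (PPI) networks, built
around the analysis design used for tumour-grade comparisons in expression
studies (e.g. colon cancer grade II vs grade III): a small two-group
expression experiment is reduced to a candidate biomarker panel by combining
differential expression, network topology and gene-set enrichment.

The pipeline, end to end:

1. **DEG selection** — median-center each sample, rank genes by a two-sample
   t-test on log2 intensities, keep the top *N* = 250 and then only genes
   with linear fold change FC < 0.5 or FC > 2, where
   FC = 2^(mean_B − mean_A) on the log2 scale.
2. **Network topology** — build a simple undirected graph from an edge list
   (TSV or SIF), extract the main connected component, and compute per node:
   degree, Brandes betweenness centrality normalized by (N−1)(N−2)/2, and
   closeness CC(v) = (N−1)/Σ_u d(v,u). The degree distribution is fitted as
   count = a·k^b by least squares on log–log axes (a scale-free network has
   b < 0); R² is computed on the logarithmized values.
3. **Node selection** — *hubs*: degree ≥ mean + 2·SD (sample SD);
   *central*: top 5% by betweenness and top 5% by closeness (exactly
   ⌈0.05·N⌉ each, deterministic tie-breaks), combined by intersection;
   *critical*: hubs ∩ central — the biomarker panel.
4. **Enrichment** — right-tailed hypergeometric test of the critical set
   against GMT gene sets, Holm step-down adjustment, %G/T = 100·k/K per
   term, and term clustering by Cohen's kappa of membership vectors
   (edge at κ ≥ 0.4, clusters = connected components).

A first-class synthetic-data module generates all inputs with the assumed
statistical structure (planted fold changes, preferential-attachment
networks, random annotations), and a packaged curated table ships the 34
enrichment terms annotated to the six-gene colon-cancer panel
{MAPK3, AKT1, SRC, TP53, GAPDH, ALB}.

## Worked example

Simulate a complete input bundle (1000 genes, 3 + 3 samples, 50 planted
DEGs with log2 effect 3 and noise SD 0.5; a 150-node scale-free network
over the planted genes plus 100 added interactors; 50 random annotation
terms), then run the pipeline:

```bash
critnet simulate --output-dir demo --seed 1
critnet run --config demo/config.yaml
```

which prints

```
wrote synthetic bundle to demo
critical set (7): G0013, G0031, G0055, G0086, G0252, G0342, G0448
report written to demo/results/report.json
```

The report records 64 DEGs surviving the top-250 + fold-change filter, a
main component of 150 nodes / 444 edges, a degree-distribution fit
b = −1.732 with R² = 0.877 (scale-free shape), 10 hubs, and a 7-gene
critical set. The enrichment table is empty, as it should be: the simulated
annotations carry no signal, and the Holm-adjusted hypergeometric test
finds nothing at α = 0.05.

The packaged curated table works the same way from Python:

```python
from critnet import colon_grade_terms, membership_counts, cluster_terms

rows, panel = colon_grade_terms()          # 34 terms, 6-gene panel
membership_counts(rows, sorted(panel))
# {'AKT1': 32, 'ALB': 0, 'GAPDH': 1, 'MAPK3': 34, 'SRC': 22, 'TP53': 17}
clusters = cluster_terms(rows, threshold=0.4, universe=set(panel))
# every term joins one cluster except the HIF-1 signaling row (its own cluster)
```

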