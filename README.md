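# netage

Integrative network analysis of gene expression across young, aging and
Alzheimer's disease (AD) brain samples: signed weighted co-expression module
discovery with trait correlation, cell-type enrichment and permutation-based
module preservation, plus an expression-weighted protein–protein interaction
(PPI) overlay that detects differentially connected edges via weighted
edge-betweenness centrality and extracts up/downregulated subnetworks with
degree-ranked hubs.

It is written for systems-biology analysts who want the whole
young → aging → AD pipeline as tested, reusable Python — from a normalized
expression matrix (TSV or GEO series-matrix text) to module/trait tables,
differential-expression and enrichment statistics, preservation Z-scores and
differential PPI subnetworks — together with a synthetic-data module that
plants known structure so every stage has a ground-truth benchmark.

## The models in brief

**Co-expression.** Signed similarity S_ij = (1 + cor(x_i, x_j))/2; adjacency
a_ij = S_ij^β with β chosen by the scale-free topology criterion (signed R² of
log p(k) vs log k); topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); modules are
long-lived branches of the average-linkage dendrogram of 1 − TOM (minimum
size 150), summarised by eigengenes (first singular vector of the
standardized module expression), correlated with age, ordinal stage
(young 0 / aging 1 / AD 2) and AD status, and ranked internally by
intramodular connectivity kIM.

**Statistics.** Empirical-Bayes moderated t-tests (posterior variance
shrinkage with moment-matched prior) with BH correction and a fold-change
≥ 1.5 / adjusted p < 0.05 DEG rule; one-sided Fisher exact (hypergeometric
tail) module × cell-type overlap; permutation Zsummary preservation
(density + connectivity composite; < 2 none, 2–10 weak-moderate, > 10
strong).

**Weighted PPI.** Node weight N_i = condition-specific linear intensity; edge
weight W_ij = 1/(N_i·N_j) acts as a distance, so weighted edge betweenness
concentrates on high-expression corridors.  Edges whose betweenness differs
between conditions beyond a magnitude threshold with BH-corrected
significance form the up/downregulated subnetworks; their high-degree nodes
are the hubs.

See `docs/methods.md` for assumptions, parameter defaults, calibration
regimes and known limitations.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
with planted ground truth (each writes tables under `results/`):

```bash
python analysis/01_simulate_study.py      # expression + markers + perturbed PPI
python analysis/02_coexpression_modules.py
python analysis/03_module_statistics.py
python analysis/04_ppi_differential_network.py
python analysis/05_benchmark_summary.py
```

Step 01 simulates 2,000 genes × 56 samples (17 young / 21 aging / 18 AD) with
four planted modules — two upregulated, two downregulated across the
young → aging → AD transition — and a 200-node scale-free PPI in which one
hub edge (`G00038–G00013`) is doubled in AD.  The subsequent steps print:

```
soft-threshold power: 13
modules found: {1: 300, 2: 250, 3: 200, 4: 160} (0 = unassigned: 1090 genes)
  M1: stage correlation +0.63 (p = 2.59e-07)
  M2: stage correlation +0.52 (p = 4.27e-05)
  M3: stage correlation -0.60 (p = 8.86e-07)
  M4: stage correlation -0.50 (p = 7.49e-05)
young vs aging: 162 up, 97 down DEGs (fold change >= 1.5, BH-adjusted p < 0.05)
aging vs ad: 354 up, 60 down DEGs ...
young vs ad: 555 up, 365 down DEGs ...
  module M1: Zsummary = 78.1 (strong)
  module M2: Zsummary = 16.0 (strong)
  module M3: Zsummary = 15.4 (strong)
  module M4: Zsummary = 4.0 (weak-moderate)
young vs ad: 29 differentially connected edges (16 up, 13 down)
  up-subnetwork hubs: G00038
```

Reading this: all four planted modules are recovered exactly (the benchmark
summary reports module ARI 1.0), their eigengene–stage correlations carry the
planted signs, the DEG counts grow with the young→AD distance as planted,
three of four modules replicate strongly in an independent draw (the weakest,
within-module correlation 0.6, lands in the weak-moderate band — see the
preservation caveats in the methods note), and the perturbed hub gene G00038
tops the upregulated subnetwork of the young-vs-AD contrast; the benchmark
summary confirms both perturbed genes are flagged.

The same machinery runs on real data: `ExpressionDataset.from_tsv` /
`read_expression(..., format="series_matrix")`, probe collapse by maximal
IQR, the `IQR > 0.2` variance filter, and age/diagnosis stratification into
young (20–50), aging (70–99) and AD (70–99) groups are all in
`netage.expression_io`, and `netage.pipeline.run_pipeline` orchestrates every
stage from a single `RunConfig` with a reproducibility manifest.

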