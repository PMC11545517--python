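# gclayers

Layer-based transcriptomic stratification of tumour cohorts, built for
the gastric-adenocarcinoma setting: given a gene × sample expression
matrix and a clinical table, the package extracts successive
"biological layers" — disjoint gene blocks that each carry their own
partition of the samples — and turns them into a prognostic molecular
classification.

The pipeline chains:

1. **Pre-processing** — log2 transform, ≥75%-valid gene filtering,
   left-censored normal imputation (width 0.3, downshift 1.8), top-2000
   most-variable gene selection.
2. **Molecular subtyping** — a multiclass SAM statistic
   d_g = √BMS_g / (s_g + s0) with permutation FDR defines a
   differential panel among labeled samples; unlabeled samples are
   assigned to the CIN/MSI/GS/EBV centroid with the highest Pearson
   correlation.
3. **Functional network** — a decomposable Gaussian graphical model
   over genes (maximum-likelihood spanning forest, then greedy forward
   edge search minimizing BIC = −2 log L + k·log n under a chordality
   constraint), partitioned into branches whose enriched annotation
   defines per-sample functional-node activities.
4. **Layer discovery** — recursive sparse k-means (Witten–Tibshirani:
   maximize Σ_g w_g·BCSS_g s.t. ‖w‖₂ ≤ 1, ‖w‖₁ ≤ s) + consensus
   clustering; each round's selected genes form a layer and leave the
   pool, so layers are disjoint by construction.
5. **Combined molecular layer (CML)** — the union of designated layers'
   gene panels, consensus-clustered into prognostic groups and
   cross-tabulated against subtypes (chi-squared / Fisher).
6. **Survival** — Kaplan–Meier curves and medians, log-rank tests, and
   Cox hazard ratios between groups.

A first-class synthetic-cohort generator plants exactly this structure
(layer blocks, subtype labels, exponential survival, missingness) with
full ground truth, so every stage is validated by recovery tests.

## Worked example

`examples/04_layer_discovery.py` plants three disjoint layers (30, 25
and 20 genes; two 2-group and one 3-group partition, effect size δ = 6)
among 75 background genes over 90 samples, then runs the recursion:

```
discovered 3 layers
  layer 1: 30 genes, k=2, PAC=0.00 -> planted block 1 (gene F1=1.00, label ARI=1.00)
  layer 2: 25 genes, k=2, PAC=0.00 -> planted block 2 (gene F1=1.00, label ARI=1.00)
  layer 3: 20 genes, k=3, PAC=0.00 -> planted block 3 (gene F1=1.00, label ARI=1.00)
```

Each discovered layer matches one planted block exactly (gene F1 and
label ARI of 1.0), the group counts 2/2/3 are recovered, and PAC = 0
means every consensus entry was unambiguous. On the default emulated
cohort (`examples/01_simulate_cohort.py`):

```
matrix: 2000 genes x 142 samples, 5591 missing entries
layer block sizes: [118, 97, 46, 125, 116, 65, 104]
subtype counts: {'CIN': 77, 'MSI': 27, 'GS': 29, 'EBV': 9}
survival: 29 events / 142 samples
```

i.e. seven planted blocks totalling 671 genes, the emulated subtype mix
(54.2/19.0/20.5/6.3%), and a lightly-censored survival profile.
`examples/05_cml_and_survival.py` carries a cohort through CML
construction and survival comparison, ending in

```
log-rank: chi2=31.77 (df=1), p=1.73e-08
HR=0.11 (95% CI 0.05-0.28)
```

— the CML groups separate the planted survival difference (the group
with the planted log-HR of 1.3 dies faster; the HR is printed for the
second-named group relative to the first).

The other examples cover pre-processing + centroid subtyping (02), the
functional network and node activities (03), and the full config-driven
pipeline (06). A thin CLI wraps the same functions:

```sh
gclayers simulate --outdir cohort/
gclayers preprocess cohort/expression.tsv --pre-logged --out processed.tsv
gclayers layers processed.tsv --outdir layers/
gclayers run --config pipeline.yaml
```

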