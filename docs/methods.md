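# Methods

`gclayers` re-implements, as a tested library, a layer-based
stratification workflow for bulk tumour transcriptomes, exercised end to
end on a synthetic gastric-adenocarcinoma-like cohort. This note records
the models, the defaults and why they are what they are, and the known
limits of what the test suite demonstrates.

## Pre-processing (`gclayers.preprocess`)

Raw abundances are log2-transformed with a pseudocount (default offset
1.0; 0 for strictly positive pre-logged input). Genes with ≥ 75% valid
(non-missing, finite) values are kept — the boundary is inclusive, and
zeros count as valid. Remaining missing values are imputed per sample
column from Normal(mean − 1.8·sd, (0.3·sd)²), the "replace from normal
distribution" scheme for left-censored log-scale data with its
conventional width/downshift defaults; this assumes missingness
concentrated in the low-abundance tail, which is also how the synthetic
generator plants it (MCAR — see limitations). Finally the 2000 genes
with the largest sample SD (unbiased, n−1 denominator; ties broken by
gene id) are retained. Filtering is idempotent and imputation never
touches observed entries — both are property-tested.

## Molecular subtyping (`gclayers.subtypes`)

A multiclass SAM-type statistic scores each gene:

d_g = sqrt(BMS_g) / (s_g + s0),

where BMS_g = Σ_k n_k (x̄_gk − x̄_g)² / (K−1) is the between-class mean
square and s_g the pooled within-class SD. The fudge factor s0 is the
percentile of {s_g} minimizing the coefficient of variation of d across
SD-ordered gene bins (evaluated on a 0–100% grid in steps of 5). The
exact multiclass normalization constant differs between SAM
implementations; because inference is by permutation of the class
labels, every monotone variant gives identical calls, so the package
uses the ANOVA-numerator form above. False discovery is controlled the
SAM way: for each gene's threshold, expected false positives are the
mean permutation count of statistics at least as large, divided by the
observed call count, then monotonized into q-values; genes with
q < 0.05 form the differential panel (defaults: 100 permutations,
exhaustive enumeration whenever the number of distinct label
arrangements is smaller).

Per-subtype centroids are mean expression over the panel. Unlabeled
samples are assigned to the subtype with the highest Pearson
correlation; the assignment is invariant to positive affine transforms
of the profile, and ties (broken by centroid order) are logged. Whether
the centroid panel is the SAM set (default) or the whole 2000-gene
working set is a configuration switch, since either reading of the
source workflow is defensible.

## Decomposable Gaussian network (`gclayers.network`)

Genes are modelled jointly Gaussian on the log scale. Structure search
maximizes the decomposable-model BIC in two stages:

1. **ML spanning forest.** Edge weight −(n/2)·log(1−r²_uv); the
   maximum-weight spanning tree is pruned of edges whose BIC change
   n·log(1−r²) + log n is non-negative (penalty: log n per free
   parameter; the model counts p means, p variances, one parameter per
   edge).
2. **Forward search.** Candidate edges are non-adjacent pairs with a
   common neighbour. In a chordal graph the common neighbourhood
   S = N(u)∩N(v) of such a pair is necessarily complete (otherwise a
   chordless 4-cycle would already exist), so the likelihood change of a
   decomposability-preserving addition is −(n/2)·log(1−ρ²_{uv·S}) with ρ
   the partial correlation given S, giving ΔBIC = n·log(1−ρ²) + log n.
   Candidates are tried best-first and accepted only if the graph passes
   a full maximum-cardinality-search chordality re-check. The search
   stops when no candidate improves the BIC.

Chordality is decided by MCS with the Tarjan–Yannakakis
perfect-elimination check; the test suite verifies it against exhaustive
chordless-cycle enumeration on every graph with up to 6 vertices, and
verifies that the incremental ΔBIC matches a from-scratch
clique/separator factorized BIC (junction tree built from a
maximum-weight spanning tree of the clique-intersection graph). When
data are drawn from 4-variable decomposable Gaussian models (n = 500),
the greedy search attains the global optimum over all decomposable
graphs in every tested draw. Under dense unstructured covariances it
does not and cannot: there are draws where no single edge improves the
BIC but a pair of edges jointly does, and draws where the ML tree is
not a subgraph of the optimum — inherent limits of single-edge forward
search, not implementation defects.

**Branches.** The source workflow divides the network into functional
branches without stating the algorithm. The package removes the
highest-betweenness edge (deterministic lexicographic tie-break) until
every component is below a size cap (or a target branch count is
reached), then merges undersized components into the neighbour they
share most original edges with. Branch annotation is a hypergeometric
overrepresentation test against user GMT sets with Benjamini–Hochberg
correction, with the background equal to the working gene set — matching
selection-conditioned inference rather than a whole-genome background.
A functional node's activity is the unweighted mean expression of the
branch genes annotated to the branch's top function (all branch genes,
optionally).

## Sparse k-means (`gclayers.sparse_kmeans`)

The Witten–Tibshirani formulation: maximize Σ_g w_g·BCSS_g over
non-negative weights with ‖w‖₂ ≤ 1 and ‖w‖₁ ≤ s, alternating k-means on
sqrt(w)-scaled genes with the closed-form weight update
w ∝ (BCSS − Δ)₊, where Δ ≥ 0 is bisected so the L1 bound binds
(Δ = 0 when slack). Convergence: relative L1 weight change < 1e-4 or 20
rounds; best of 10 restarts by objective. Genes are z-scored before
fitting. The sparsity bound is tuned by the permutation gap statistic
gap(s) = log O(s; data) − mean log O(s; gene-wise permuted data) over a
small geometric grid, argmax by default (one-SE rule optional). The gap
keeps every truly informative gene but leaves long tails of tiny noise
weights, so "selected genes" throughout the package means weight above
10% of the maximum weight. The cut is null-calibrated: for a fixed
balanced split, a structureless z-scored gene's between-cluster sum of
squares is approximately χ²₁ while a genuine block gene's is of order
n·δ²/(δ²+4), so a 10% relative cut leaves a per-gene chance crossing
probability around half a percent yet keeps every gene of a
homogeneous-effect block. With 10 informative genes planted among 200,
the tuned fit selects ≈ 5% of genes and the informative set is complete.

## Consensus clustering (`gclayers.consensus`)

Per candidate k: 500 subsamples (80% of samples without replacement) are
k-means-clustered (10 restarts); the consensus matrix M is the
co-cluster count over the co-sample count. Both the consensus-CDF
delta-area and the PAC (fraction of off-diagonal entries in (0.1, 0.9))
are computed for every k. **k is selected by minimum PAC** (ties to the
smaller k): the CDF area grows with k even on structureless data, which
makes the raw argmax-delta-area rule drift upward on unbalanced groups
(observed on planted two-group data with a 0.6/0.4 split whose consensus
matrix was exactly binary); PAC-based selection is the
literature-standard correction and the delta-area remains available via
`criterion="delta"`. Final labels are average-linkage hierarchical
clusters of 1 − M cut at k*.

## Recursive layer discovery (`gclayers.layers`)

Each round, on the surviving (re-z-scored) gene pool: sparse k-means is
tuned and fitted for each k in the range; fits are compared across k by
objective per cluster dimension O/(k−1), because the raw weighted BCSS
grows mechanically with k; the winning fit's selected genes form the
candidate layer; consensus clustering restricted to those genes fixes k*
and the labels; the layer's genes leave the pool. Rounds are accepted
only if

- the permutation gap of the winning fit exceeds max(0.3, 2 permutation
  SDs). Stability alone is not a safe stopping rule here: the consensus
  matrix is computed on genes chosen to support the split, so pure-noise
  matrices produce small "layers" with PAC < 0.2 in roughly half of
  runs. The gap separates the two regimes by an order of magnitude in
  calibration runs against the generator's null (structureless gaps
  ≤ ~0.13 at the cohort sizes used; genuinely layered rounds ≥ 1.3 even
  at effect size 2), and 0.3 sits well above the selection-bias
  inflation of the null; and
- the consensus PAC is ≤ 0.4 (`stop_pac`).

Recursion also ends at 7 layers (the emulated study's count) or when the
pool drops below 20 genes. Layer gene sets are disjoint by construction;
full-run determinism for a fixed seed is tested.

## Combined molecular layer and cross-tabulation (`gclayers.cml`)

The CML is the union of designated layers' gene sets (disjointness is
asserted — a violated recursion contract raises). With the emulated
layer sizes (118, 97, 125, 116 for layers 1, 2, 4, 5) the CML has
exactly 456 genes. Samples are consensus-clustered on the CML panel;
groups are named CML1..CMLk by ascending size, a deterministic
convention (real cohorts attach meaning by cross-tabulation against
reference labels, reported as a greedy best-overlap mapping). Redundant
layer pairs (label ARI > 0.7) are reported with a warning, not
auto-excluded; the inclusion list is explicit configuration.

Association tests follow a fixed rule: 2×2 tables use Fisher's exact
test when any expected count is below 5, otherwise chi-squared with
Yates correction; larger tables use plain chi-squared, falling back to a
seeded Monte-Carlo Fisher test (100 000 Patefield draws of tables with
the observed margins, ordered by hypergeometric probability) when
expected counts are small. All p-values are two-sided.

## Survival statistics (`gclayers.survival`)

Kaplan–Meier curves use the product-limit estimator with censorings
ordered after tied events; the median is the smallest t with
S(t) ≤ 0.5 and is reported as "not reached" when S never crosses 0.5.
Group comparison is the standard log-rank chi-squared (df = groups − 1).
Two-group hazard ratios come from a single-covariate Cox partial
likelihood with Efron tie handling (Newton–Raphson via lifelines), with
a 95% Wald interval — a deliberate choice over the cruder O/E ratio
some point-and-click tools report. Functional-node activities are
compared by Mann–Whitney U (exact enumeration when the pooled n ≤ 12
and tie-free, tie-corrected normal approximation otherwise) or
Kruskal–Wallis, with Dunn's BH-adjusted post-hoc available. Calibration
is part of the acceptance suite: log-rank type-I error 5% ± 2% under H0
and mean Cox β̂ within 0.1 of log 3 under a true HR of 3.

## Synthetic cohorts (`gclayers.synthetic`)

The generator plants exactly the structure the analysis assumes:
disjoint layer gene blocks, each with its own sample partition;
background noise genes; subtype labels; survival; MCAR missingness.
Defaults are the emulated study's conditions: 142 samples, seven blocks
of 118/97/46/125/116/65/104 genes (2-group except the 3-group seventh,
group proportions as reported), 2000 genes total, subtype mix
54.2/19.0/20.5/6.3% (CIN/MSI/GS/EBV). Expression is
baseline_g + sign_g·δ·group + N(0, noise_sd²) on the log2 scale with
per-gene baselines N(8, 2²); noise_sd = 1 and δ = 2 are calibration
choices (the source data's noise model is unobservable), with δ = 6
used in recovery benchmarks, which target the high-signal regime. Subtype labels are drawn first to match the target
mix, and the two designated "subtype-concordant" layers inherit their
partitions from the subtypes (CIN/MSI vs GS/EBV and CIN/EBV vs MSI/GS)
with a 10% label-flip rate — implementing "subtypes are a function of
two layers" in the proportion-preserving direction. Survival is
exponential proportional hazards with independent exponential
censoring; baseline 0.012/month and censoring 0.055/month give ≈ 25
events per 142 samples at a ~15-month median follow-up, matching the
emulated cohort, with default log-HRs (0, 1.1) on the driving layer.

What the generator does **not** emulate: count noise and library-size
effects, batch structure, gene–gene correlation within a block beyond
the shared group shift, informative missingness, EBV-specific biology.
Passing recovery tests therefore demonstrates correctness of the
algorithms under their own assumptions, not performance on real RNA-seq.

## Problem sizes used in tests and the acceptance script

Recovery and calibration suites run at reduced, fixed sizes chosen once:
planted-layer recovery uses 3 blocks of 30/25/20 genes + 75 background
over 90 samples with 100 consensus resamples (25 seeds in the test
suite, 12 in the acceptance script); sparse k-means recovery uses the
10-of-200-gene model over 60 samples (50 seeds, s = √10, the oracle
sparsity of the planted block); end-to-end determinism runs the full
pipeline twice on a 60-sample, 220-gene configuration; exhaustive
chordality sweeps cover all 6-vertex graphs in the test suite and all
5-vertex graphs in the script; forward-search optimality uses 4-variable
models (100 draws in tests, 60 in the script). The emulated full-size
defaults (142 × 2000) remain the package defaults.

## Known limitations

- The branch-partitioning algorithm and the layer-acceptance gate are
  this package's own constructions for steps the source workflow leaves
  unspecified; alternatives (e.g. community detection for branches)
  could relabel boundaries.
- The delta-area criterion is retained but not default; users comparing
  against ConsensusClusterPlus habits should expect PAC-based k.
- Greedy forward BIC search is optimal on the small models tested, not
  in general; with 2000 genes the edge budget (`max_added_edges`)
  bounds runtime and the result depends on it.
- SAM q-values use the conservative π0 = 1 convention.
- At the default stop_pac = 0.4 and without the gap gate, weakly
  supported layers can be accepted; the gate is on by default and can be
  disabled (`min_gap=0`) to reproduce the purely PAC-gated behaviour.
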