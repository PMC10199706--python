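# Methods

This note documents the statistical model behind `plastiscan`, the
assumptions of its synthetic-data generator, and every numerical choice
that was genuinely open.

## Study design

The pipeline targets fully crossed factorial bulk RNA-seq designs with four
categorical factors — cultivar (2 levels), tissue (2), developmental stage
(3, ordered), soil (3) — and *r* biological replicates per combination
(default 3, i.e. 36 conditions × 3 = 108 samples).  `SampleDesign` enforces
the complete crossing; samples and conditions are ordered by nesting
cultivar → tissue → stage → soil → replicate, which fixes the column order
of every profile matrix.

## Normalization and variance stabilization

Between-sample scaling uses the trimmed mean of M-values (TMM): for each
library *j* against a reference *r* (the sample whose 75th percentile of
library-relative expression is closest to the mean of those percentiles),
per-gene log-ratios `M_g = log2((x_gj/N_j)/(x_gr/N_r))` and average
abundances `A_g` are computed over genes expressed in both libraries, the
top and bottom 30% by M and 5% by A are trimmed (rank-based, average ranks
for ties), and the factor is `2^(Σ w_g M_g / Σ w_g)` with inverse
asymptotic-variance weights.  Factors are rescaled to geometric mean 1.
These are the standard Robinson–Oshlack conventions; the implementation is
checked both against an independently coded literal-formula oracle (1e-10)
and against Bioconductor's `edgeR::calcNormFactors` (1e-6).

The variance-stabilizing transform is `log2(CPM_TMM + prior)` with prior
count 0.5.  This is a deliberately simple, deterministic realization of
"VST": its contract — that the log-variance vs log-mean slope of replicate
groups drops from ≈2 (raw NB counts) to ≈0 — is what the tests enforce, and
the transform sits behind one function (`normalization.vst`) so a fitted
dispersion-based transform can be swapped in.  The prior bounds values below
by `log2(prior)` and caps the variance of low counts.

## Screening

Genes are labeled in a fixed order; the first matching label wins:

| label | rule | default |
|---|---|---|
| unexpressed | fewer than `min_expressed_samples` samples with CPM ≥ floor | floor 1.0, 3 samples |
| constitutive | CV of the 36 condition-mean CPMs < `cv_floor` | 0.05 |
| outlier | 1..`outlier_max_samples` samples with robust z > `outlier_z` | z 6.0, ≤2 samples |

Numerical choices: the flatness CV is computed on **linear-scale** CPM
condition means — on the log scale a single 75-fold spike moves the CV by
less than 0.05, and with the fixed check order an outlier gene would be
mislabeled constitutive.  The outlier z-score is `(x−median)/(1.4826·MAD)`
per gene on the VST scale and **one-sided** (upward): "outlier expression"
means an inflated sample, and a two-sided rule would flag the compressed
low tail of smooth log-scale profiles.  When MAD is zero (a majority of
identical values) the standard deviation substitutes so a lone spike
remains visible.  The thresholds are declared package defaults — exposed as
arguments and logged in the report — because no canonical values exist for
these three filters; what is reproducible is the decision rule.

## Clustering

Each retained gene is reduced to its 36 condition means and z-standardized
(mean 0, unit variance per gene) so that profile *shape* drives membership;
expression *level* differences are captured later by the VIMs.  k-means
(best inertia over 25 seeded restarts) partitions the profiles; centroids
are recomputed as member means, `variance_explained` is between-cluster SS
over total SS, and the homogeneity index *Rc* of a cluster is the mean
Pearson correlation between member profiles and the centroid (singletons
score 1; zero-variance members are excluded with a warning).  *Rc* is
scale-free and, for moderately noisy synthetic clusters, lands in the
0.7–0.9 band reported for real co-expression clusters.  `choose_k` returns
the smallest grid *k* whose variance explained reaches the target share
(default 0.80), warning and falling back to the largest feasible *k*
otherwise; *k* values with persistently empty clusters (fewer distinct
profiles than *k*) are skipped with a warning.  Ties are broken by fixed
seed, best inertia, lowest cluster id.

## Variable importance

Per gene, a gradient-boosted regression-tree ensemble (LightGBM) models VST
expression from the one-hot-encoded factors.  Hyperparameters are fixed and
logged: 500 trees, depth 3 (8 leaves), learning rate 0.05, 80% row
subsampling per tree, minimum 5 samples per leaf (the library default of 20
blocks depth-3 splits at n = 108).  `VIM_v` is the total split gain
attributable to factor *v*'s columns, summed over all trees (relative
influence); consequently `Σ_v VIM_v` equals the ensemble's total gain, a
conservation law the tests verify against the dumped tree structures.
Constant genes get all-zero VIMs and a flag.  Per-gene seeds derive
deterministically from one base seed.

Cluster VIMs are the medians of member-gene VIMs (a per-centroid mode
exists for speed: the centroid profile is broadcast to samples and modeled
once per cluster).  Ranks are assigned per variable, descending, ties
broken by cluster id.  The four top-*k* rank sets (default *k* = 30, capped
at the cluster count) are partitioned exactly by membership bitmask into
variable-specific and shared categories.

Pairwise interaction strength is Friedman's H: with centered partial
dependences `PD_v`, `H²(v,w) = Σ ŵ·(PD_vw − PD_v − PD_w)² / Σ ŵ·PD_vw²`
over the joint level grid, weighted by empirical level-pair frequencies;
the reported statistic is `H = √H² ∈ [0,1]`.  Partial dependences are
computed exactly by overwrite-and-average, which is cheap for categorical
factors.

## PCA crossing

Sample PCA (samples as observations, genes centered internally) and cluster
profile PCA (conditions as observations, clusters as features) use an SVD
with the sign convention that each loading vector's largest-magnitude entry
is positive.  A design variable is associated with the component whose
per-cluster |loadings| maximize |Spearman ρ| against that variable's
cluster VIMs — a scale-free realization of "crossing" importance with
component structure; the ρ value is reported alongside the component.

## Soil differential-expression screen

Within each cultivar × tissue × stage stratum (9 samples), a one-way
fixed-effects ANOVA F-test of soil is applied to VST values per gene, with
Benjamini–Hochberg adjustment within the stratum; DEG flags are kept at
both p < 0.01 and FDR < 0.05.  This is a documented substitution for a
count-based GLM: the validated surface is **calibration** — type-I error at
nominal 0.05 within [0.03, 0.07] on null NB genes and power ≥ 0.9 for
log2FC-3 soil effects at dispersion 0.05 with n = 3/soil — not numeric
identity with any particular GLM implementation.  DEG sets are intersected
by exact membership partition (private = member of exactly one set).

## Phenology dendrogram

E-L series are divided by the dataset median, distances are `d = 1 − r`
(Pearson; the simplest reading of converting correlations to distances —
`1 − |r|` and `√(2(1−r))` would also be defensible and the distance matrix
is exposed), and merged by average linkage.  Constant series are rejected.
Export to Newick goes through scikit-bio.

## Enrichment

*Terms*: upper-tail hypergeometric p for the overlap between a study set
and each term's genes over a declared universe, BH across terms, fold
enrichment = observed/expected.  *Motifs*: PWMs are per-position log2-odds
against a background (default uniform; promoter-set composition
configurable).  The best score of a motif in a promoter is the maximum over
all offsets on both strands; `N` positions contribute 0, so an all-N
sequence scores 0; ties resolve to the smallest offset, forward strand
first.  Group enrichment compares best scores of a gene group against the
rest with Welch's t-test (pooled-variance behind a flag; degenerate
comparisons fall back to t = 0, p = 1), BH across the motif panel.
*Peaks*: a (TF, gene) link is retained iff the peak **midpoint** falls in
the closed window [−2000, 0] bp of the gene's TSS, strand-aware (upstream
negative); midpoints are robust to peak width.  Because "x in common (y%)"
statements are ambiguous about their denominator, the overlap report emits
the percentage under every candidate denominator (each set and the union).

## Synthetic-data generator

The generator defines the study conditions the tests run under:

* **Counts**: NB with `Var = μ + μ²·φ` (the mean/dispersion
  parameterization standard in RNA-seq; no noise model is canonical for
  this design, so it is declared here).  Library factors are log-normal, sd 0.3, geometric mean 1
  — large enough that TMM is non-trivial.  Gene baselines are jittered
  log-normally (sd 0.3) within an archetype so members share shape, not
  level.
* **Archetypes**: the six-archetype benchmark panel has one archetype per
  single driver (stage, cultivar, tissue, soil), one pure stage × soil
  interaction, and one undriven block.  Effects are **centered** (down- as
  well as up-regulation, graded −½..+½ of the log2 fold-change across a
  factor's levels) and the default full-study composition keeps driven
  blocks at ~20–25% of genes with a large undriven background
  (tissue > stage > cultivar > soil block sizes, mirroring the usual
  variance hierarchy of berry RNA-seq).  Both choices exist because TMM
  assumes a mostly non-differential transcriptome with roughly symmetric
  M-values; an all-differential, all-upregulated matrix leaves a systematic
  ~8% condition-level wobble in CPM space that no scaling normalization can
  remove, and genuinely flat genes then fail the CV < 0.05 flatness call.
* **Inadequate genes** overwrite randomly chosen rows (means track each
  sample's empirical depth so planting survives normalization):
  unexpressed ≈ Poisson(0.001); constitutive = one expected mean in every
  condition with dispersion 5e-4 (far below biological noise — that *is*
  the label's meaning); outlier = a flat profile with exactly one sample
  inflated 75-fold (≥ 50 required).
* **Promoters**: i.i.d. background of configurable composition (default
  uniform), one PWM-sampled site per bound promoter at a uniform offset and
  random strand — the simplest identifiable design — plus a binding peak
  whose midpoint lies in −2000..−100 of the (strand-aware) TSS.
* **Phenology**: the default E-L template is a two-phase logistic
  (budburst→flowering rise to ~E-L 12 by day 40, lag phase, then
  véraison→harvest rise to ~E-L 38 around day 140, 8-day scales), sampled
  weekly over 210 days; this mirrors the fast/slow alternation of real
  seasonal staging, and weekly sampling of such a curve resolves a 7-day
  lag.  A scalar `soil_offset` applies graded lags 0, d, 2d across the
  soils so that every soil is distinguishable (a mapping argument lags
  individual soils, e.g. a single late soil).  Noise is Gaussian in E-L
  units, and series are clipped to be non-decreasing.

What the generator does **not** emulate: gene–gene correlation beyond the
shared archetype profile, GC or length biases, multi-site promoters,
isoform structure, batch effects, or count overdispersion heterogeneity
within an archetype.  Passing tests therefore demonstrate that the
pipeline's inferences are correct when its distributional assumptions hold
and are calibrated against planted truth — not that real tissue or soil
effects of a given size will be recovered from any particular field
experiment.

## Problem sizes

The test suite and the acceptance script run end-to-end benchmarks at
1,800–2,200 genes × 108 samples (per-gene boosting dominates at roughly
0.05 s/gene), 5,500 genes for ANOVA calibration, 800 × 600-bp promoters ×
21 motifs for the group test, and 50 seeded phenology runs.  These sizes
give stable pass/fail margins for every property while keeping a full run
in the minutes range on one CPU.

## Known limitations

* The VST is a shifted log, not a fitted mean–dispersion transform; at very
  low counts residual mean–variance dependence remains.
* TMM inherits its mostly-non-differential assumption; under strongly
  asymmetric global expression shifts all relative-scaling normalizations
  (including this one) leave residual compositional bias.
* The soil screen is an ANOVA on transformed values, not a count GLM; at
  n = 3/group its power against small effects is limited and its type-I
  calibration relies on the VST making NB noise approximately homoskedastic.
* Split-gain VIMs share the known bias of tree importances toward
  predictors with more categories; with 2–3 levels per factor the effect is
  mild, and a permutation-importance mode would be the remedy if factors
  with many levels were added.
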