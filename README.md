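# plastiscan

Which experimental variable drives transcriptome variation — developmental
stage, cultivar, tissue, or soil?  `plastiscan` implements a three-step
statistical pipeline for fully crossed factorial bulk RNA-seq designs,
motivated by studies of grapevine berry phenotypic plasticity where the soil
is isolated from all other *terroir* variables:

1. **Screening** — discard genes with inadequate profiles (unexpressed,
   constitutive, single-sample outliers) after TMM normalization and a
   variance-stabilizing transform;
2. **Co-expression clustering** — k-means on per-gene condition-mean
   profiles (z-standardized so shape, not level, drives membership), with a
   homogeneity index *Rc* (mean member–centroid Pearson correlation) and the
   share of variance explained used to choose *k*;
3. **Variable importance** — per-gene gradient-boosted regression trees of
   expression on the four factors; the VIM of a factor is its total
   split-gain (relative influence).  Cluster-median VIMs are ranked per
   variable and the four top-*k* rank sets are intersected to call
   *variable-specific* and *variable-shared* clusters.  Friedman's
   H statistic quantifies pairwise factor interactions.

Around this core the package provides PCA of samples and of cluster
profiles crossed with VIM ranks, a per-stratum one-way soil ANOVA screen
with BH-FDR and DEG set intersections, a correlation-distance phenology
dendrogram, hypergeometric term enrichment, best-PWM-score promoter group
tests, a −2000..0 bp TSS-window filter for TF-binding peak tables — and a
synthetic study generator that emulates the full 2 cultivar × 2 tissue ×
3 stage × 3 soil × 3 replicate (108-sample) design with complete ground
truth (planted archetypes, inadequate genes, motif sites, enriched terms,
soil-lagged phenology), so every stage of the pipeline is testable against
what was planted.

## The model in brief

Counts are negative-binomial, `Var = μ + μ²·φ`, with per-gene means
`μ_gs = b_g · 2^(Σ effects at sample s's factor levels) · L_s` for a
log-normal library factor `L_s`.  Expression is analyzed as
`log2(CPM_TMM + 0.5)`.  For a factor *v* with one-hot columns in a boosted
ensemble of trees, `VIM_v = Σ_trees Σ_{splits on v} ΔSSE` — the classical
split-gain importance, so `Σ_v VIM_v` equals the ensemble's total gain.
A cluster's rank `Rnk_VIM_v` orders the cluster-median VIMs (1 = most
important); a cluster is *soil-specific* if it is in the top-*k* for soil
and no other variable.

## Worked example

```python
import plastiscan as ps
from plastiscan.synthetic import default_archetypes, make_design, simulate_counts

design = make_design({"cultivar": 2, "tissue": 2, "stage": 3, "soil": 3}, replicates=3)
counts, truth = simulate_counts(design, default_archetypes(fold_change=4.0,
                                                           dispersion=0.05),
                                genes_per_archetype=300, seed=5)
factors = ps.tmm_factors(counts)
expr = ps.vst(counts, factors)
profiles = ps.standardize_profiles(ps.condition_means(expr, design))
clusters = ps.kmeans_clusters(profiles, k=6, seed=0)
print(f"variance explained: {clusters.variance_explained:.3f}")
print("Rc:", {c: round(v, 2) for c, v in clusters.rc.items()})

vims = ps.cluster_vims(ps.fit_vims(expr, design, seed=0), clusters)
print(vims.table[["VIM_soil", "Rnk_VIM_soil"]].round(1))
```

prints

```
variance explained: 0.909
Rc: {1: 0.96, 2: 0.98, 3: 0.97, 4: 0.96, 5: 0.94, 6: 0.91}
         VIM_soil  Rnk_VIM_soil
cluster
1           343.2             1
2           105.5             4
3           102.0             5
4           107.0             3
5           146.4             2
6           100.9             6
```

Six clusters reproduce the six planted archetypes (variance explained 0.91;
high *Rc* means the average profile represents its members well), and
cluster 1 — the planted soil archetype — ranks first on `VIM_soil` with a
median importance ~3× every other cluster, i.e. the pipeline attributes its
expression pattern to the soil factor.

The same analyses are available from a shell:

```bash
plastiscan simulate --seed 5 --out data/
plastiscan screen  --data data/ --out screened/
plastiscan cluster --data data/ --expression screened/expression_retained.tsv --k 6 --out clustered/
plastiscan vim     --data data/ --expression screened/expression_retained.tsv \
                   --clusters clustered/clusters.tsv --k-top 2 --out vims/
plastiscan anova   --data data/ --out deg/
```

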