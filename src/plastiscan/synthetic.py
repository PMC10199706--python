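"""Synthetic factorial RNA-seq study generator with full ground truth.

Emulates a berry-transcriptome experiment: a complete crossing of
2 cultivars x 2 tissues x 3 developmental stages x 3 soils with 3 biological
replicates (108 samples), negative-binomial counts driven by gene
"archetypes" (each archetype names the factor(s), possibly one two-way
interaction, that modulate its genes), planted inadequate-profile genes
(unexpressed / constitutive / single-sample outlier), promoter sequences
with planted PWM sites and TSS-proximal binding peaks, annotation terms with
a planted enrichment, and phenology (E-L stage) time series with per-soil
developmental lags.

Every stage returns a :class:`~plastiscan.containers.SyntheticTruth` so each
downstream analysis can be scored against what was planted.  All randomness
flows from one integer seed through a named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (DEFAULT_LEVELS, FACTORS, CountMatrix, SampleDesign,
                         SyntheticTruth, _auto_levels)
from .enrichment import ALPHABET, PWM, TermMap, reverse_complement

EffectKey = tuple[str, str]  # (factor, level)
InteractionKey = tuple[EffectKey, EffectKey]


@dataclass(frozen=True)
class GeneArchetype:
    """Expression program shared by a block of genes.

    ``log2_effects`` maps (factor, level) to an additive log2 fold effect;
    ``interaction_log2_effects`` maps a pair of (factor, level) keys to an
    extra effect applied only when both levels co-occur (one two-way
    interaction).  Counts for a gene follow NB(mean, dispersion) with
    variance = mu + mu^2 * dispersion.
    """

    name: str
    baseline_mean: float
    dispersion: float
    log2_effects: Mapping[EffectKey, float] = field(default_factory=dict)
    interaction_log2_effects: Mapping[InteractionKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError(f"archetype {self.name}: baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError(f"archetype {self.name}: dispersion must be positive")

    @property
    def driver_variables(self) -> frozenset[str]:
        drivers = {f for (f, _lvl) in self.log2_effects}
        for (a, b) in self.interaction_log2_effects:
            drivers.add(a[0])
            drivers.add(b[0])
        return frozenset(drivers)


def make_design(levels_per_factor: Mapping[str, int | Sequence[str]],
                replicates: int) -> SampleDesign:
    """Complete-crossing sample sheet, factors nested in the order
    cultivar, tissue, stage, soil, with replicate innermost.

    Factor levels may be given as counts (named automatically, grapevine
    study names for the default sizes) or explicit level-name sequences.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    levels: dict[str, tuple[str, ...]] = {}
    for factor in FACTORS:
        if factor not in levels_per_factor:
            raise ValueError(f"missing factor: {factor}")
        spec = levels_per_factor[factor]
        if isinstance(spec, int):
            if spec < 1:
                raise ValueError(f"factor {factor} must have >= 1 level")
            levels[factor] = _auto_levels(factor, spec)
        else:
            lv = tuple(str(x) for x in spec)
            if not lv:
                raise ValueError(f"factor {factor} must have >= 1 level")
            levels[factor] = lv
    rows = []
    for c in levels["cultivar"]:
        for t in levels["tissue"]:
            for s in levels["stage"]:
                for o in levels["soil"]:
                    for r in range(1, replicates + 1):
                        rows.append((f"{c}.{t}.{s}.{o}.r{r}", c, t, s, o, r))
    table = pd.DataFrame(rows, columns=["sample_id", *FACTORS, "replicate"])
    table = table.set_index("sample_id")
    return SampleDesign(table, levels)


def _sample_log2_effects(arch: GeneArchetype, design: SampleDesign) -> np.ndarray:
    """Per-sample total log2 effect of one archetype."""
    tab = design.table
    total = np.zeros(design.n_samples)
    for (factor, level), eff in arch.log2_effects.items():
        if factor not in FACTORS:
            raise ValueError(f"unknown factor in archetype {arch.name}: {factor}")
        if level not in design.levels[factor]:
            raise ValueError(f"unknown level {level!r} of factor {factor}")
        total += np.where(tab[factor].values == level, eff, 0.0)
    for ((f1, l1), (f2, l2)), eff in arch.interaction_log2_effects.items():
        mask = (tab[f1].values == l1) & (tab[f2].values == l2)
        total += np.where(mask, eff, 0.0)
    return total


def simulate_counts(design: SampleDesign,
                    archetypes: Sequence[GeneArchetype],
                    genes_per_archetype: int | Sequence[int],
                    seed: int,
                    lib_sigma: float = 0.3,
                    baseline_jitter_sigma: float = 0.3,
                    ) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a gene x sample NB count matrix from archetype programs.

    Gene g in sample s has mean ``baseline_g * 2^(sum of archetype effects
    at s's levels) * L_s`` where L_s is a log-normal library-size factor
    (sd ``lib_sigma``, geometric mean 1).  Baselines are jittered
    log-normally around the archetype baseline so genes within an archetype
    share shape but not level.
    """
    if not archetypes:
        raise ValueError("need at least one archetype")
    if isinstance(genes_per_archetype, int):
        sizes = [genes_per_archetype] * len(archetypes)
    else:
        sizes = list(genes_per_archetype)
        if len(sizes) != len(archetypes):
            raise ValueError("genes_per_archetype length mismatch")
    rng = np.random.default_rng(seed)
    lib = rng.lognormal(0.0, lib_sigma, design.n_samples)
    lib /= np.exp(np.log(lib).mean())
    blocks = []
    gene_ids: list[str] = []
    archetype_of: dict[str, str] = {}
    offset = 0
    for arch, n_genes in zip(archetypes, sizes):
        fx = 2.0 ** _sample_log2_effects(arch, design)
        base = arch.baseline_mean * rng.lognormal(0.0, baseline_jitter_sigma, n_genes)
        mu = base[:, None] * fx[None, :] * lib[None, :]
        size = 1.0 / arch.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
        blocks.append(counts)
        ids = [f"G{offset + i + 1:05d}" for i in range(n_genes)]
        gene_ids.extend(ids)
        archetype_of.update({g: arch.name for g in ids})
        offset += n_genes
    counts = pd.DataFrame(np.vstack(blocks), index=gene_ids,
                          columns=design.sample_ids)
    truth = SyntheticTruth(seed=seed, archetype_of=archetype_of)
    return CountMatrix(counts, design), truth


def plant_inadequate_genes(matrix: CountMatrix,
                           n_unexpressed: int = 0,
                           n_constitutive: int = 0,
                           n_outlier: int = 0,
                           seed: int = 0,
                           unexpressed_mean: float = 0.001,
                           flat_mean: float = 2000.0,
                           flat_sigma: float = 0.4,
                           flat_dispersion: float = 5e-4,
                           outlier_factor: float = 75.0,
                           ) -> tuple[CountMatrix, SyntheticTruth]:
    """Overwrite random genes with inadequate expression profiles.

    * unexpressed: near-zero Poisson counts in every sample;
    * constitutive: identical expected mean in every condition, with
      dispersion far below biological noise so the profile is flat;
    * outlier: a flat profile with exactly one sample inflated
      ``outlier_factor`` (>= 50) fold.

    Planted means scale with each sample's empirical library depth so the
    planting survives library-size normalization.
    """
    if outlier_factor < 50:
        raise ValueError("outlier_factor must be >= 50 to stand clear of NB noise")
    n_total = n_unexpressed + n_constitutive + n_outlier
    if n_total == 0:
        return matrix, SyntheticTruth()
    if n_total > len(matrix.genes):
        raise ValueError(f"cannot plant {n_total} genes into a "
                         f"{len(matrix.genes)}-gene matrix")
    rng = np.random.default_rng(seed)
    counts = matrix.counts.copy()
    depth = matrix.library_sizes.values.astype(float)
    rel_depth = depth / depth.mean()
    chosen = rng.choice(len(matrix.genes), size=n_total, replace=False)
    labels = (["unexpressed"] * n_unexpressed + ["constitutive"] * n_constitutive
              + ["outlier"] * n_outlier)
    inadequate: dict[str, str] = {}
    n_samples = matrix.counts.shape[1]
    for idx, label in zip(chosen, labels):
        gene = matrix.genes[idx]
        if label == "unexpressed":
            row = rng.poisson(unexpressed_mean * rel_depth)
        else:
            mu = flat_mean * rng.lognormal(0.0, flat_sigma) * rel_depth
            size = 1.0 / flat_dispersion
            row = rng.negative_binomial(size, size / (size + mu))
            if label == "outlier":
                j = rng.integers(n_samples)
                spike_mu = mu[j] * outlier_factor
                row[j] = rng.negative_binomial(size, size / (size + spike_mu))
        counts.iloc[idx] = row
        inadequate[gene] = label
    return CountMatrix(counts, matrix.design), SyntheticTruth(inadequate=inadequate)


def default_archetypes(fold_change: float = 4.0,
                       dispersion: float = 0.05,
                       baseline_mean: float = 300.0,
                       levels: Mapping[str, Sequence[str]] = DEFAULT_LEVELS,
                       ) -> list[GeneArchetype]:
    """The six-archetype benchmark panel: one archetype per single driver
    (stage, cultivar, tissue, soil), one stage x soil interaction, and one
    undriven 'none' archetype.  ``fold_change`` is the ratio between the
    most and least expressed level of the driving factor.
    """
    top = float(np.log2(fold_change))
    cultivar, tissue, stage, soil = (levels[f] for f in FACTORS)

    def graded(factor: str, lvls: Sequence[str]) -> dict[EffectKey, float]:
        # centered effects (down- as well as up-regulation) keep the M-value
        # distribution of differential genes symmetric, as TMM assumes
        k = len(lvls)
        if k < 2:
            return {}
        return {(factor, lv): top * (i / (k - 1) - 0.5) for i, lv in enumerate(lvls)}

    return [
        GeneArchetype("stage", baseline_mean, dispersion, graded("stage", stage)),
        GeneArchetype("cultivar", baseline_mean, dispersion, graded("cultivar", cultivar)),
        GeneArchetype("tissue", baseline_mean, dispersion, graded("tissue", tissue)),
        GeneArchetype("soil", baseline_mean, dispersion, graded("soil", soil)),
        GeneArchetype("stage_x_soil", baseline_mean, dispersion, {},
                      {(("stage", stage[-1]), ("soil", soil[-1])): top}),
        GeneArchetype("none", baseline_mean, dispersion, {}),
    ]


# ---------------------------------------------------------------------------
# promoters, peaks, annotations


def random_pwm(width: int, rng: np.random.Generator, name: str = "pwm",
               concentration: float = 0.3) -> PWM:
    """Random informative PWM: per-position Dirichlet(concentration) columns.

    Small ``concentration`` yields sharp (information-rich) positions, as in
    real TF motifs.
    """
    probs = rng.dirichlet([concentration] * 4, size=width)
    return PWM.from_probabilities(probs, name=name)


def simulate_promoters(genes: Sequence[str],
                       pwm: PWM,
                       bound_set: Iterable[str],
                       seed: int,
                       length: int = 600,
                       background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                       tf_name: str | None = None,
                       chrom: str = "chr1",
                       spacing: int = 10_000,
                       peak_width_range: tuple[int, int] = (120, 400),
                       ) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Promoter FASTA-ready sequences, a BED-style peak table and a TSS table.

    Background bases are i.i.d. from ``background``; each gene in
    ``bound_set`` receives one site sampled from the PWM at a random offset
    and strand, plus a binding peak whose midpoint falls within -2000..0 bp
    of the gene's TSS (strand-aware genomic coordinates).

    Returns ``(promoters, peaks, tss_table, truth)``.
    """
    bound = list(dict.fromkeys(bound_set))
    if not set(bound) <= set(genes):
        raise ValueError("bound_set is not a subset of genes")
    if pwm.width > length:
        raise ValueError("PWM wider than the promoter")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg < 0).any():
        raise ValueError("background must be 4 non-negative frequencies")
    bg = bg / bg.sum()
    rng = np.random.default_rng(seed)
    tf = tf_name or pwm.name
    base_arr = np.array(list(ALPHABET))
    site_probs = pwm.site_probabilities()

    promoters: dict[str, str] = {}
    motifs: dict[str, dict] = {}
    tss_rows = []
    peak_rows = []
    for i, gene in enumerate(genes):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = 5_000 + i * spacing
        tss_rows.append((gene, chrom, tss, strand))
        seq = "".join(base_arr[rng.choice(4, size=length, p=bg)])
        if gene in set(bound):
            site = "".join(base_arr[rng.choice(4, p=site_probs[j])]
                           for j in range(pwm.width))
            site_strand = "+" if rng.random() < 0.5 else "-"
            placed = site if site_strand == "+" else reverse_complement(site)
            offset = int(rng.integers(0, length - pwm.width + 1))
            seq = seq[:offset] + placed + seq[offset + pwm.width:]
            motifs[gene] = {"offset": offset, "strand": site_strand,
                            "site": site, "tf": tf}
            mid_offset = float(rng.uniform(-1_900, -100))
            width = int(rng.integers(*peak_width_range))
            mid = tss + mid_offset if strand == "+" else tss - mid_offset
            start = int(round(mid - width / 2))
            end = start + width
            peak_rows.append((chrom, start, end, tf, gene, 0, strand))
        promoters[gene] = seq
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "tf",
                                             "gene", "score", "strand"])
    tss_table = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand"])
    tss_table = tss_table.set_index("gene")
    truth = SyntheticTruth(seed=seed, motifs=motifs)
    return promoters, peaks, tss_table, truth


def simulate_annotations(genes: Sequence[str],
                         n_terms: int,
                         seed: int,
                         enriched: Mapping[str, tuple[Sequence[str], float]] | None = None,
                         background_rate: float = 0.05,
                         ) -> tuple[TermMap, SyntheticTruth]:
    """Gene -> term annotations with planted enrichments.

    ``enriched`` maps a term id to ``(target_genes, planted_fraction)``: the
    term annotates exactly ``round(fraction * len(target))`` target genes
    plus non-target genes at ``background_rate``.  The ``n_terms``
    background terms annotate every gene at ``background_rate``.
    """
    if not 0 <= background_rate <= 1:
        raise ValueError("background_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    terms: dict[str, set[str]] = {}
    truth_terms: dict[str, dict] = {}
    for i in range(n_terms):
        mask = rng.random(len(genes)) < background_rate
        terms[f"T{i + 1:04d}"] = {g for g, m in zip(genes, mask) if m}
    for term, (target, fraction) in (enriched or {}).items():
        if not 0 <= fraction <= 1:
            raise ValueError("planted fraction must be in [0, 1]")
        target = list(target)
        if not set(target) <= set(genes):
            raise ValueError(f"term {term}: target genes outside the universe")
        n_hit = int(round(fraction * len(target)))
        hits = set(rng.choice(target, size=n_hit, replace=False)) if n_hit else set()
        others = [g for g in genes if g not in set(target)]
        bg_mask = rng.random(len(others)) < background_rate
        annotated = hits | {g for g, m in zip(others, bg_mask) if m}
        terms[term] = annotated
        truth_terms[term] = {"target": target, "fraction": fraction,
                             "planted": sorted(hits)}
    return TermMap(terms, set(genes)), SyntheticTruth(seed=seed, terms=truth_terms)


# ---------------------------------------------------------------------------
# phenology


def default_el_template(t: np.ndarray | float) -> np.ndarray:
    """Season-long E-L (Eichhorn-Lorenz) development curve, days -> E-L stage.

    Two logistic phases reproduce the shape of real seasonal staging: a fast
    budburst-to-flowering rise (~E-L 12 by day 40), a lag phase, then the
    veraison-to-harvest rise to ~E-L 38 around day 140.
    """
    t = np.asarray(t, dtype=float)
    return (12.0 / (1.0 + np.exp(-(t - 40.0) / 8.0))
            + 26.0 / (1.0 + np.exp(-(t - 140.0) / 8.0)))


def simulate_phenology(design: SampleDesign,
                       soil_offset: float | Mapping[str, float],
                       noise_sd: float,
                       seed: int,
                       dates: Sequence[float] | None = None,
                       template: Callable[[np.ndarray], np.ndarray] = default_el_template,
                       ) -> pd.DataFrame:
    """Per-replicate phenology series (rows) over weekly dates (columns).

    One series per cultivar x soil x replicate.  ``soil_offset`` is either a
    mapping soil -> developmental lag in days, or a scalar d applied as
    graded lags 0, d, 2d, ... across the soils in design order (so every
    soil is distinguishable).  Gaussian noise (sd in E-L units) is added and
    the series is clipped to be non-decreasing in time.
    """
    soils = design.levels["soil"]
    if isinstance(soil_offset, Mapping):
        offsets = {s: float(soil_offset.get(s, 0.0)) for s in soils}
    else:
        offsets = {s: float(soil_offset) * i for i, s in enumerate(soils)}
    if dates is None:
        dates = np.arange(0.0, 211.0, 7.0)
    dates = np.asarray(dates, dtype=float)
    rng = np.random.default_rng(seed)
    rows = {}
    for cultivar in design.levels["cultivar"]:
        for soil in soils:
            for rep in range(1, design.n_replicates + 1):
                curve = template(dates - offsets[soil])
                noisy = curve + rng.normal(0.0, noise_sd, size=dates.size)
                rows[f"{cultivar}.{soil}.r{rep}"] = np.maximum.accumulate(noisy)
    return pd.DataFrame(rows, index=dates).T


# ---------------------------------------------------------------------------
# one-call study bundle


@dataclass
class SyntheticStudy:
    """Everything the pipeline consumes, plus the merged ground truth."""

    counts: CountMatrix
    truth: SyntheticTruth
    promoters: dict[str, str]
    peaks: pd.DataFrame
    tss: pd.DataFrame
    term_map: TermMap
    phenology: pd.DataFrame
    pwm: PWM


#: default block sizes of the study transcriptome: the driven blocks mirror
#: the usual variance hierarchy of berry RNA-seq (tissue > stage > cultivar
#: > soil) and together stay well below the TMM trim fraction, as TMM's
#: mostly-non-differential assumption requires.
DEFAULT_ARCHETYPE_SIZES: dict[str, int] = {
    "stage": 150, "cultivar": 90, "tissue": 180, "soil": 60,
    "stage_x_soil": 60, "none": 120,
}


def simulate_study(seed: int,
                   archetype_sizes: Mapping[str, int] | None = None,
                   n_background: int = 1540,
                   n_unexpressed: int = 100,
                   n_constitutive: int = 100,
                   n_outlier: int = 100,
                   fold_change: float = 4.0,
                   dispersion: float = 0.05,
                   replicates: int = 3,
                   motif_consensus: str = "GGTAGGTG",
                   soil_offset: float = 7.0,
                   phenology_noise_sd: float = 0.5,
                   ) -> SyntheticStudy:
    """Generate the full default study: 108-sample factorial counts with the
    six-archetype panel plus an undriven background block and planted
    inadequate genes, promoters with the consensus motif planted in the
    soil-archetype genes, annotation terms enriched in the same genes, and
    soil-lagged phenology.
    """
    rng = np.random.default_rng(seed)
    design = make_design({"cultivar": 2, "tissue": 2, "stage": 3, "soil": 3},
                         replicates=replicates)
    sizes = dict(DEFAULT_ARCHETYPE_SIZES)
    sizes.update(archetype_sizes or {})
    panel = default_archetypes(fold_change, dispersion)
    panel = [a for a in panel if sizes.get(a.name, 0) > 0]
    if n_background > 0:
        panel.append(GeneArchetype("background", 300.0, dispersion))
        sizes["background"] = n_background
    counts, truth = simulate_counts(
        design, panel, [sizes[a.name] for a in panel],
        seed=int(rng.integers(2**31)))
    counts, planted = plant_inadequate_genes(
        counts, n_unexpressed, n_constitutive, n_outlier,
        seed=int(rng.integers(2**31)))
    truth = truth.merge(planted)
    soil_genes = sorted(g for g, a in truth.archetype_of.items() if a == "soil")
    pwm = PWM.from_consensus(motif_consensus, name="planted")
    promoters, peaks, tss, motif_truth = simulate_promoters(
        counts.genes, pwm, soil_genes, seed=int(rng.integers(2**31)))
    truth = truth.merge(motif_truth)
    term_map, term_truth = simulate_annotations(
        counts.genes, n_terms=20, seed=int(rng.integers(2**31)),
        enriched={"T_soil": (soil_genes, 0.5)})
    truth = truth.merge(term_truth)
    phenology = simulate_phenology(design, soil_offset, phenology_noise_sd,
                                   seed=int(rng.integers(2**31)))
    return SyntheticStudy(counts, truth, promoters, peaks, tss, term_map,
                          phenology, pwm)
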