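"""Term and promoter-motif enrichment.

Three independent analyses share this module:

* hypergeometric over-representation of annotation terms in a study set;
* the "best PWM score per promoter" group test: instead of thresholding
  motif hits into bound/unbound calls, the maximum log-odds score of each
  motif over every promoter (both strands) is recorded and a two-sample
  t-test compares a gene group against the rest, with BH correction across
  motifs;
* a TSS-window filter of TF-binding peak tables, keeping genes whose peak
  midpoint falls within a fixed upstream window (default -2000..0 bp),
  with multi-set overlap reporting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix as per-position log2-odds against a background.

    ``matrix`` has shape (width, 4) over the alphabet ACGT.  Ambiguous (N)
    positions in a scanned sequence contribute 0 to a window score, so an
    all-N sequence scores 0.
    """

    matrix: np.ndarray  # (width, 4) log2-odds
    name: str = "pwm"
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must be (width, 4) with width >= 1")
        if not np.isfinite(m).all():
            raise ValueError("PWM matrix must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], name=self.name, background=self.background)

    @classmethod
    def from_probabilities(
        cls,
        probs: np.ndarray,
        name: str = "pwm",
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudo: float = 1e-3,
    ) -> "PWM":
        p = np.asarray(probs, dtype=float)
        if (p < 0).any():
            raise ValueError("probabilities must be non-negative")
        p = (p + pseudo) / (p + pseudo).sum(axis=1, keepdims=True)
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
        return cls(np.log2(p / bg), name=name, background=tuple(bg))

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "pwm",
                    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                    pseudo: float = 0.5) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudo
        return cls.from_probabilities(c / c.sum(axis=1, keepdims=True), name=name,
                                      background=background, pseudo=0.0)

    @classmethod
    def from_consensus(cls, consensus: str, name: str | None = None,
                       match_prob: float = 0.94) -> "PWM":
        """Near-deterministic PWM whose preferred base carries ``match_prob``."""
        consensus = consensus.upper()
        if any(b not in _BASE_INDEX for b in consensus):
            raise ValueError("consensus must be over ACGT")
        off = (1.0 - match_prob) / 3.0
        p = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            p[i, _BASE_INDEX[b]] = match_prob
        return cls.from_probabilities(p, name=name or consensus, pseudo=0.0)

    def site_probabilities(self) -> np.ndarray:
        """Per-position base probabilities implied by the log-odds and background."""
        bg = np.asarray(self.background)
        p = (2.0 ** self.matrix) * bg
        return p / p.sum(axis=1, keepdims=True)

    def log_odds_of(self, site: str) -> float:
        """Score of one width-length site on the forward strand."""
        if len(site) != self.width:
            raise ValueError("site length must equal PWM width")
        return float(sum(0.0 if b == "N" else self.matrix[i, _BASE_INDEX[b]]
                         for i, b in enumerate(site.upper())))


def read_jaspar(path) -> list[PWM]:
    """Read PWMs from a JASPAR-format plain-text count matrix file."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
        out.append(PWM.from_counts(counts, name=m.matrix_id or m.name or "pwm"))
    return out


def write_jaspar(pwms: Iterable[PWM], path, scale: float = 100.0) -> None:
    """Write PWMs as JASPAR-style count matrices (probabilities x ``scale``)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            p = pwm.site_probabilities() * scale
            fh.write(f">{pwm.name} {pwm.name}\n")
            for j, b in enumerate(ALPHABET):
                vals = " ".join(f"{v:.2f}" for v in p[:, j])
                fh.write(f"{b}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# promoter scanning


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an int8 matrix (A,C,G,T -> 0..3, N -> 4)."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return lut[arr].reshape(len(seqs), lengths.pop())


def _strand_scores(encoded: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Window scores (n_seq x n_offsets) of one strand; N contributes 0."""
    n, length = encoded.shape
    w = matrix.shape[0]
    if length < w:
        raise ValueError("sequence shorter than PWM width")
    m = np.hstack([matrix, np.zeros((w, 1))])  # 5th column: N scores 0
    n_off = length - w + 1
    scores = np.zeros((n, n_off))
    for j in range(w):
        scores += m[j, encoded[:, j:j + n_off]]
    return scores


def best_scores(seqs: Sequence[str], pwm: PWM) -> pd.DataFrame:
    """Best log-odds hit of ``pwm`` in each sequence, scanning both strands.

    Ties are resolved to the smallest offset, forward strand first.  Offsets
    are 0-based positions of the hit start on the forward sequence.
    """
    enc = encode_sequences(seqs)
    fwd = _strand_scores(enc, pwm.matrix)
    rev = _strand_scores(enc, pwm.reverse_complement().matrix)
    n = enc.shape[0]
    n_off = fwd.shape[1]
    # interleave [fwd@0, rev@0, fwd@1, rev@1, ...] so that the first argmax
    # realizes the tie-break: smallest offset, forward strand before reverse
    interleaved = np.empty((n, 2 * n_off))
    interleaved[:, 0::2] = fwd
    interleaved[:, 1::2] = rev
    idx = interleaved.argmax(axis=1)  # first max wins: smallest offset, fwd first
    best = interleaved[np.arange(n), idx]
    offs = idx // 2
    strands = np.where(idx % 2 == 0, "+", "-")
    return pd.DataFrame({"score": best, "offset": offs, "strand": strands})


def pwm_best_score(seq: str, pwm: PWM) -> tuple[float, int, str]:
    """Best hit of ``pwm`` in a single sequence: (score, offset, strand)."""
    row = best_scores([seq], pwm).iloc[0]
    return float(row["score"]), int(row["offset"]), str(row["strand"])


def score_panel(promoters: Mapping[str, str], pwms: Sequence[PWM]) -> pd.DataFrame:
    """Best score of every PWM (columns) in every promoter (rows)."""
    genes = list(promoters)
    seqs = [promoters[g] for g in genes]
    cols = {}
    for pwm in pwms:
        cols[pwm.name] = best_scores(seqs, pwm)["score"].values
    return pd.DataFrame(cols, index=genes)


# ---------------------------------------------------------------------------
# hypergeometric term enrichment


@dataclass
class TermMap:
    """term id -> annotated gene set, over a background universe."""

    terms: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for t, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {t} annotates genes outside the universe")


def hypergeom_enrich(study: Iterable[str], term_map: TermMap,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term.

    ``p = P(overlap >= observed)`` drawing ``|study|`` genes without
    replacement from the universe; fold enrichment is observed/expected.
    """
    study = set(study)
    if not term_map.universe:
        raise ValueError("empty gene universe")
    if not study <= term_map.universe:
        raise ValueError("study set not contained in the universe")
    M = len(term_map.universe)
    n = len(study)
    rows = []
    for term, genes in term_map.terms.items():
        K = len(genes)
        k = len(study & genes)
        expected = n * K / M
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        fold = k / expected if expected > 0 else np.nan
        rows.append((term, k, K, expected, fold, p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "expected",
                                      "fold_enrichment", "p"]).set_index("term")
    if len(out):
        out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
        out["significant"] = out["fdr"] < alpha
    return out.sort_values("p")


# ---------------------------------------------------------------------------
# best-score group test


def motif_group_test(scores: pd.DataFrame, group: Iterable[str],
                     equal_var: bool = False) -> pd.DataFrame:
    """Compare best-score distributions of a gene group against the rest.

    ``scores`` is genes x motifs (from :func:`score_panel`).  A Welch
    two-sample t-test per motif (pooled-variance via ``equal_var=True``),
    BH-corrected across motifs.  Degenerate comparisons (singleton group
    with zero spread) fall back to t=0, p=1.
    """
    group = [g for g in scores.index if g in set(group)]
    if not group:
        raise ValueError("empty group")
    rest = scores.index.difference(group)
    if len(rest) == 0:
        raise ValueError("group equals the whole universe; nothing to compare")
    a = scores.loc[group]
    b = scores.loc[rest]
    rows = []
    import warnings as _warnings
    for motif in scores.columns:
        x, y = a[motif].values, b[motif].values
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # near-constant groups -> t=0, p=1 below
            t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        if not np.isfinite(t):
            t, p = 0.0, 1.0
        rows.append((motif, float(np.mean(x)), float(np.mean(y)), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["motif", "group_mean", "rest_mean", "t", "p"])
    out = out.set_index("motif")
    out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out.sort_values("p")


# ---------------------------------------------------------------------------
# TSS-window peak filter


def promoter_window_filter(peaks: pd.DataFrame, tss: pd.DataFrame,
                           window: tuple[float, float] = (-2000.0, 0.0)) -> pd.DataFrame:
    """Keep (TF, gene) links whose peak midpoint lies in a TSS-relative window.

    ``peaks`` columns: chrom, start, end (0-based half-open), tf, gene,
    strand optional per-row; ``tss`` is indexed by gene with columns chrom,
    tss, strand.  Offsets are strand-aware: negative = upstream of the TSS.
    Returns the peak table with ``offset`` and ``retained`` columns.
    """
    lo, hi = window
    required = {"chrom", "start", "end", "tf", "gene"}
    if not required <= set(peaks.columns):
        raise ValueError(f"peak table needs columns {sorted(required)}")
    missing = set(peaks["gene"]) - set(tss.index)
    if missing:
        raise ValueError(f"peaks reference genes without TSS entries: {sorted(missing)[:5]}")
    strands = tss.loc[peaks["gene"], "strand"].values
    if not np.isin(strands, ["+", "-"]).all():
        raise ValueError("unknown strand in TSS table")
    mid = (peaks["start"].values + peaks["end"].values) / 2.0
    t = tss.loc[peaks["gene"], "tss"].values.astype(float)
    offset = np.where(strands == "+", mid - t, t - mid)
    out = peaks.copy()
    out["offset"] = offset
    out["retained"] = (offset >= lo) & (offset <= hi)
    return out


def retained_gene_sets(filtered_peaks: pd.DataFrame) -> dict[str, set[str]]:
    """Per-TF set of genes with at least one retained peak."""
    kept = filtered_peaks[filtered_peaks["retained"]]
    return {tf: set(sub["gene"]) for tf, sub in kept.groupby("tf")}


def overlap_report(gene_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exact membership partition of multiple gene sets.

    One row per non-empty membership combination, with the shared count and
    the percentage under every candidate denominator (each set and the
    union), since "x in common (y%)" statements are ambiguous about their
    denominator.
    """
    names = list(gene_sets)
    union = set().union(*gene_sets.values()) if gene_sets else set()
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(gene_sets[n] for n in combo))
            outside = set().union(*(gene_sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            exclusive = inside - outside
            row = {"sets": "&".join(combo), "n_exclusive": len(exclusive),
                   "n_intersection": len(inside)}
            for n in names:
                denom = len(gene_sets[n])
                row[f"pct_of_{n}"] = 100.0 * len(inside) / denom if denom else np.nan
            row["pct_of_union"] = 100.0 * len(inside) / len(union) if union else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
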