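"""Independent brute-force reference implementations used as test oracles.

Everything here is written against the literal textbook formulas with plain
loops, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def average_ranks(values):
    """1-based ranks with ties sharing their average rank (no scipy)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for kk in range(i, j + 1):
            ranks[order[kk]] = avg
        i = j + 1
    return ranks


def tmm_reference(counts: np.ndarray, trim_M: float = 0.30, trim_A: float = 0.05):
    """Literal trimmed-mean-of-M-values factors, gene loops and all."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    rates = counts / lib
    f75 = np.array([np.quantile(rates[:, j], 0.75) for j in range(n_samples)])
    ref = min(range(n_samples), key=lambda j: abs(f75[j] - f75.mean()))
    factors = []
    for j in range(n_samples):
        Ms, As, ws = [], [], []
        for g in range(n_genes):
            o, r = counts[g, j], counts[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            Ms.append(math.log2(po / pr))
            As.append((math.log2(po) + math.log2(pr)) / 2.0)
            ws.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not Ms or max(abs(m) for m in Ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(Ms)
        loM = math.floor(n * trim_M) + 1
        hiM = n + 1 - loM
        loA = math.floor(n * trim_A) + 1
        hiA = n + 1 - loA
        rM = average_ranks(Ms)
        rA = average_ranks(As)
        num = den = 0.0
        for m, a, w, km, ka in zip(Ms, As, ws, rM, rA):
            if loM <= km <= hiM and loA <= ka <= hiA:
                num += m / w
                den += 1.0 / w
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    factors = np.array(factors)
    log_mean = sum(math.log(f) for f in factors) / len(factors)
    return factors / math.exp(log_mean)


def bh_reference(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, literal definition."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adjusted[i] = running
    return np.array(adjusted)


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n), by exact enumeration."""
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return float(total)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_best_hit(seq: str, matrix: np.ndarray):
    """Exhaustive scan of every window on both strands.

    ``matrix`` is the forward-strand (width, 4) log-odds over ACGT; N scores
    0.  Returns (score, offset, strand) with ties to smallest offset,
    forward strand first.
    """
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = len(matrix)
    rc = "".join(_COMP[b] for b in reversed(seq))

    def window_score(s, start):
        total = 0.0
        for j in range(w):
            b = s[start + j]
            if b != "N":
                total += matrix[j][base_idx[b]]
        return total

    best = None
    hits = []  # every (offset, strand) within float noise of the maximum
    for offset in range(len(seq) - w + 1):
        for strand in "+-":
            if strand == "+":
                sc = window_score(seq, offset)
            else:
                # a reverse-strand hit starting at forward offset `offset`
                # covers rc positions len-w-offset .. len-offset
                sc = window_score(rc, len(seq) - w - offset)
            if best is None or sc > best[0]:
                best = (sc, offset, strand)
            hits.append((sc, offset, strand))
    ties = {(o, s) for sc, o, s in hits if abs(sc - best[0]) < 1e-9}
    return best[0], best[1], best[2], ties


def one_way_f_reference(groups):
    """Textbook one-way fixed-effects ANOVA F from a list of group value lists."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df1 = len(groups) - 1
    df2 = len(all_values) - len(groups)
    return (ssb / df1) / (ssw / df2)


def membership_partition(sets: dict):
    """gene -> frozenset of set names containing it (bitmask partition)."""
    union = set().union(*sets.values()) if sets else set()
    return {g: frozenset(name for name, s in sets.items() if g in s) for g in union}
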