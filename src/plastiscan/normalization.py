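"""Between-sample normalization and variance stabilization.

TMM (trimmed mean of M-values) computes one scaling factor per library as
the precision-weighted mean of per-gene log2 expression ratios (M) against a
reference library, after trimming the most extreme 30% of genes by M and 5%
by average log abundance (A).  Factors are rescaled to geometric mean 1.
The expression values consumed downstream are log2 counts-per-million after
TMM, with a small prior count -- a simple, deterministic variance-stabilizing
transform whose contract is that replicate variance no longer grows with the
mean (the transform is pluggable; see :func:`vst`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM scaling factors (geometric mean 1)."""

    factors: pd.Series
    reference_sample: str
    trim_M: float
    trim_A: float

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    def effective_library_sizes(self, counts: CountMatrix | pd.DataFrame) -> pd.Series:
        table = counts.counts if isinstance(counts, CountMatrix) else counts
        return table.sum(axis=0) * self.factors


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_M: float, trim_A: float) -> float:
    """Weighted trimmed mean of M-values of one library against the reference.

    Genes with zero count in either library drop out (their M or A is
    infinite); weights are the inverse asymptotic variances of M under
    binomial sampling.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logR = np.log2((obs / n_obs) / (ref / n_ref))
        absE = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(logR) & np.isfinite(absE)
    logR, absE, v = logR[keep], absE[keep], v[keep]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    lo_M = np.floor(n * trim_M) + 1
    hi_M = n + 1 - lo_M
    lo_A = np.floor(n * trim_A) + 1
    hi_A = n + 1 - lo_A
    rM = rankdata(logR)
    rA = rankdata(absE)
    kept = (rM >= lo_M) & (rM <= hi_M) & (rA >= lo_A) & (rA <= hi_A)
    if not kept.any():
        return 1.0
    f = np.sum(logR[kept] / v[kept]) / np.sum(1.0 / v[kept])
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix, trim_M: float = 0.30,
                trim_A: float = 0.05) -> NormFactors:
    """TMM scaling factors for every sample of a count matrix.

    The reference library is the sample whose 75th percentile of
    library-relative expression is closest to the mean of those percentiles.
    """
    X = counts.counts.values.astype(float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = X.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"sample has zero total count: {counts.samples[zero[0]]}")
    q75 = np.quantile(X / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array([
        _tmm_pair(X[:, j], X[:, ref_idx], lib[j], lib[ref_idx], trim_M, trim_A)
        for j in range(X.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=counts.samples),
                       counts.samples[ref_idx], trim_M, trim_A)


def cpm(counts: CountMatrix, factors: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million over the (TMM-) effective library size."""
    lib = counts.library_sizes.astype(float)
    if factors is not None:
        lib = lib * factors.factors
    # an all-zero library has no relative expression; map it to zero rather
    # than dividing by zero
    return counts.counts / lib.where(lib > 0, 1.0) * 1e6


def vst(counts: CountMatrix, factors: NormFactors | None = None,
        prior: float = 0.5) -> pd.DataFrame:
    """Variance-stabilized expression: log2(CPM + prior).

    The prior count bounds values from below (all-zero data maps to the
    constant log2(prior)) and caps the variance of low counts; on replicated
    NB data the log-variance vs log-mean slope drops from ~2 (raw counts) to
    ~0.  The returned frame records the transform in ``.attrs``.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    out = np.log2(cpm(counts, factors) + prior)
    out.attrs["transform"] = "log2_cpm"
    out.attrs["prior"] = prior
    out.attrs["tmm"] = factors is not None
    return out
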