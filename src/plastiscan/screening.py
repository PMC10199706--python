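"""Step 1 of the pipeline: discard genes with inadequate expression profiles.

Three mutually exclusive filters are applied in a fixed order before
clustering, so that only genes with a genuine, reproducible expression
pattern across conditions remain:

* unexpressed -- fewer than ``min_expressed_samples`` samples reach the CPM
  floor;
* constitutive -- expressed, but the coefficient of variation of the
  per-condition mean CPM falls below ``cv_floor`` (the profile is flat;
  condition means are used so replicate noise cannot rescue a flat gene);
* outlier -- expressed and non-constitutive, but the profile owes its
  variability to at most ``outlier_max_samples`` single samples with a
  median-absolute-deviation z-score above ``outlier_z`` on the
  variance-stabilized scale.

The thresholds are declared package defaults, exposed in the report for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .normalization import NormFactors, cpm as _cpm

STATUSES = ("retained", "unexpressed", "constitutive", "outlier")


@dataclass
class ScreeningReport:
    """Per-gene screening outcome and the metric values that produced it."""

    table: pd.DataFrame  # index gene; status, n_expressed, max_cpm, profile_cv, max_z, n_spikes
    thresholds: dict

    @property
    def retained_genes(self) -> list[str]:
        return list(self.table.index[self.table["status"] == "retained"])

    def counts(self) -> pd.Series:
        return self.table["status"].value_counts().reindex(STATUSES, fill_value=0)


def _mad_z(values: np.ndarray) -> np.ndarray:
    """Robust z-scores per row: (x - median) / (1.4826 * MAD)."""
    med = np.median(values, axis=1, keepdims=True)
    mad = np.median(np.abs(values - med), axis=1, keepdims=True)
    scale = 1.4826 * mad
    # genes with MAD 0 (more than half the samples identical): fall back to
    # the standard deviation so a lone spike is still visible
    sd = values.std(axis=1, keepdims=True)
    scale = np.where(scale > 0, scale, np.where(sd > 0, sd, 1.0))
    return (values - med) / scale


def screen_genes(expr: pd.DataFrame, counts: CountMatrix,
                 factors: NormFactors | None = None,
                 cpm_floor: float = 1.0,
                 min_expressed_samples: int = 3,
                 cv_floor: float = 0.05,
                 outlier_z: float = 6.0,
                 outlier_max_samples: int = 2,
                 ) -> tuple[ScreeningReport, pd.DataFrame]:
    """Label every gene and return the report plus the retained expression matrix.

    ``expr`` is the variance-stabilized matrix aligned with ``counts``
    (same genes and samples).
    """
    for name, value in [("cpm_floor", cpm_floor), ("cv_floor", cv_floor),
                        ("outlier_z", outlier_z),
                        ("min_expressed_samples", min_expressed_samples),
                        ("outlier_max_samples", outlier_max_samples)]:
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    if list(expr.index) != counts.genes or list(expr.columns) != counts.samples:
        raise ValueError("expression matrix not aligned with counts")

    cpm_mat = _cpm(counts, factors)
    n_expressed = (cpm_mat.values >= cpm_floor).sum(axis=1)
    unexpressed = n_expressed < min_expressed_samples

    # flatness on condition means of CPM (linear scale: a single inflated
    # condition inflates the CV, so spiked genes are not mistaken for flat)
    cond = counts.design.condition_of_samples()
    cond_means = cpm_mat.T.groupby(cond.values, observed=False).mean().T
    mean_level = cond_means.values.mean(axis=1)
    cv = np.full(len(expr), np.inf)
    ok = mean_level > 0
    cv[ok] = cond_means.values[ok].std(axis=1, ddof=1) / mean_level[ok]
    constitutive = ~unexpressed & (cv < cv_floor)

    # one-sided: outlier expression means an inflated sample; a smooth
    # profile's compressed low tail on the log scale is not a spike
    z = _mad_z(expr.values)
    n_spikes = (z > outlier_z).sum(axis=1)
    outlier = (~unexpressed & ~constitutive
               & (n_spikes >= 1) & (n_spikes <= outlier_max_samples))

    status = np.full(len(expr), "retained", dtype=object)
    status[outlier] = "outlier"
    status[constitutive] = "constitutive"
    status[unexpressed] = "unexpressed"

    table = pd.DataFrame({
        "status": status,
        "n_expressed": n_expressed,
        "max_cpm": cpm_mat.values.max(axis=1),
        "profile_cv": cv,
        "max_z": z.max(axis=1),
        "n_spikes": n_spikes,
    }, index=expr.index)
    thresholds = {"cpm_floor": cpm_floor,
                  "min_expressed_samples": min_expressed_samples,
                  "cv_floor": cv_floor, "outlier_z": outlier_z,
                  "outlier_max_samples": outlier_max_samples}
    report = ScreeningReport(table, thresholds)
    return report, expr.loc[status == "retained"]
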