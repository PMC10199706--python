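"""Per-stratum soil differential-expression screen and phenology dendrogram.

The soil screen asks, within each cultivar x tissue x stage stratum (9
samples: 3 soils x 3 replicates), which genes differ between soils.  It is a
one-way fixed-effects ANOVA F-test on variance-stabilized values with
Benjamini-Hochberg FDR per stratum -- a deliberately transparent stand-in
for a count-based GLM: the quantity validated here is calibration (type-I
error and power), not numeric identity with any particular GLM fit.

The phenology dendrogram reproduces the field-season clustering of E-L
development curves: series are normalized by the dataset median, Pearson
correlations are converted to distances (d = 1 - r) and merged by average
linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import SampleDesign


@dataclass
class DegResult:
    """Soil F-test outcome for one cultivar x tissue x stage stratum."""

    stratum: tuple[str, str, str]  # (cultivar, tissue, stage)
    table: pd.DataFrame            # index gene; F, p, fdr, deg_p01, deg_fdr05
    n_samples: int

    @property
    def label(self) -> str:
        return ".".join(self.stratum)

    def deg_set(self, criterion: str = "fdr") -> set[str]:
        col = "deg_fdr05" if criterion == "fdr" else "deg_p01"
        return set(self.table.index[self.table[col]])


def _one_way_f(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way fixed-effects F test over rows of ``values``."""
    levels = np.unique(groups)
    g = len(levels)
    n = values.shape[1]
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for lv in levels:
        sub = values[:, groups == lv]
        m = sub.mean(axis=1, keepdims=True)
        ssb += sub.shape[1] * (m[:, 0] - grand[:, 0]) ** 2
        ssw += ((sub - m) ** 2).sum(axis=1)
    df1, df2 = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(F, df1, df2)
    # genes with zero within- and between-group variance: no evidence
    degenerate = (ssw == 0) & (ssb == 0)
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, p)
    return F, p


def soil_anova(expr: pd.DataFrame, design: SampleDesign,
               cultivar: str, tissue: str, stage: str) -> DegResult:
    """One-way soil F-test within one stratum, BH-adjusted across genes."""
    tab = design.table
    mask = ((tab["cultivar"] == cultivar) & (tab["tissue"] == tissue)
            & (tab["stage"] == stage))
    samples = tab.index[mask]
    if len(samples) == 0:
        raise ValueError(f"empty stratum {cultivar}.{tissue}.{stage}")
    soils = tab.loc[samples, "soil"]
    present = set(soils)
    expected = set(design.levels["soil"])
    if present != expected:
        raise ValueError(f"stratum {cultivar}.{tissue}.{stage} misses soil "
                         f"levels: {sorted(expected - present)}")
    values = expr[samples].values
    F, p = _one_way_f(values, soils.values)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"F": F, "p": p, "fdr": fdr,
                          "deg_p01": p < 0.01, "deg_fdr05": fdr < 0.05},
                         index=expr.index)
    return DegResult((cultivar, tissue, stage), table, len(samples))


def soil_anova_all(expr: pd.DataFrame, design: SampleDesign) -> list[DegResult]:
    """The soil screen over every cultivar x tissue x stage stratum."""
    out = []
    for c in design.levels["cultivar"]:
        for t in design.levels["tissue"]:
            for s in design.levels["stage"]:
                out.append(soil_anova(expr, design, c, t, s))
    return out


def deg_intersections(gene_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Exact membership partition of DEG sets.

    Returns one row per gene in the union with boolean membership columns,
    the membership category (``&``-joined set names) and a ``private`` flag
    (member of exactly one set).
    """
    sets = {name: set(genes) for name, genes in gene_sets.items()}
    union = sorted(set().union(*sets.values())) if sets else []
    out = pd.DataFrame({name: [g in s for g in union] for name, s in sets.items()},
                       index=union)
    names = list(sets)
    member = out[names].values
    out["category"] = ["&".join(n for n, m in zip(names, row) if m) for row in member]
    out["private"] = member.sum(axis=1) == 1
    return out


# ---------------------------------------------------------------------------
# phenology dendrogram


@dataclass
class PhenologyTree:
    """Average-linkage tree over correlation distances of phenology series."""

    leaves: list[str]
    linkage: np.ndarray
    distance: pd.DataFrame
    method: str = "average"

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.leaves, name="cluster")

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.leaves)
        return str(tree).strip()


def phenology_dendrogram(pheno: pd.DataFrame, method: str = "average") -> PhenologyTree:
    """Cluster phenology series: median-normalize, d = 1 - Pearson r,
    average linkage.

    ``pheno`` holds one series per row over a shared date grid.  Constant
    series are rejected (their correlation is undefined).
    """
    if len(pheno) < 2:
        raise ValueError("need at least two series")
    X = pheno.values.astype(float)
    med = np.median(X)
    if med == 0:
        raise ValueError("dataset median is zero; cannot normalize")
    X = X / med
    sd = X.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant series: {list(pheno.index[flat][:5])}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(d, checks=False), method=method)
    return PhenologyTree(list(pheno.index), Z,
                         pd.DataFrame(d, index=pheno.index, columns=pheno.index),
                         method)
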