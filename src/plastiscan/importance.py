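"""Step 3: gradient-boosting variable importance per gene and per cluster.

For every gene, a boosted regression-tree ensemble models the
variance-stabilized expression from the four categorical factors (stage,
cultivar, tissue, soil, one-hot encoded).  The variable importance measure
(VIM) of a factor is its total split gain: the squared-error reduction of
every split on that factor, summed over all trees -- the classical
relative-influence definition.  Because boosting fits residuals iteratively,
relevant interactions are picked up without being specified a priori, and
their strength can be quantified with Friedman's H statistic.

Cluster-level VIMs are the medians of member-gene VIMs; clusters are ranked
per variable (rank 1 = most important) and the top-k sets of the four
rankings are intersected to call variable-specific and variable-shared
clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd

from .containers import FACTORS, SampleDesign
from .clustering import ClusterSet

#: column order of VIM tables
VIM_COLUMNS = tuple(f"VIM_{f}" for f in ("stage", "cultivar", "tissue", "soil"))
RANK_COLUMNS = tuple(f"Rnk_{c}" for c in VIM_COLUMNS)

DEFAULT_HYPERPARAMS: dict = {
    "n_trees": 500,
    "depth": 3,
    "learning_rate": 0.05,
    "subsample": 0.8,
    "min_leaf": 5,
}


def encode_design(design: SampleDesign) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    """One-hot encode the four factors; returns (X, factor -> column indices,
    feature names)."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for factor in FACTORS:
        groups[factor] = []
        for level in design.levels[factor]:
            groups[factor].append(len(names))
            names.append(f"{factor}={level}")
            cols.append((design.table[factor].values == level).astype(float))
    return np.column_stack(cols), groups, names


@dataclass
class GeneVim:
    """Per-gene VIMs of the four factors plus the fit summary."""

    gene: str
    vims: dict[str, float]
    constant: bool = False
    params: dict = field(default_factory=dict)
    model: lgb.Booster | None = None
    feature_groups: dict[str, list[int]] | None = None

    @property
    def total(self) -> float:
        return float(sum(self.vims.values()))


def _make_regressor(hyperparams: Mapping, seed: int) -> lgb.LGBMRegressor:
    hp = {**DEFAULT_HYPERPARAMS, **dict(hyperparams or {})}
    return lgb.LGBMRegressor(
        n_estimators=int(hp["n_trees"]),
        max_depth=int(hp["depth"]),
        num_leaves=2 ** int(hp["depth"]),
        learning_rate=float(hp["learning_rate"]),
        subsample=float(hp["subsample"]),
        subsample_freq=1,
        min_child_samples=int(hp["min_leaf"]),
        min_split_gain=0.0,
        random_state=int(seed),
        n_jobs=1,
        deterministic=True,
        verbose=-1,
    )


def fit_gene_vims(y: np.ndarray | pd.Series, design: SampleDesign,
                  hyperparams: Mapping | None = None, seed: int = 0,
                  gene: str = "", keep_model: bool = False) -> GeneVim:
    """Fit one boosted ensemble and extract per-factor total split gains.

    A constant expression profile yields all-zero VIMs and is flagged; every
    factor receives a score (0 when never split on).  Deterministic for a
    fixed seed.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("expression values must be finite")
    for factor in FACTORS:
        if len(design.levels[factor]) < 1:
            raise ValueError(f"factor {factor} has no levels")
    hp = {**DEFAULT_HYPERPARAMS, **dict(hyperparams or {})}
    X, groups, names = encode_design(design)
    if np.ptp(y) == 0.0:
        return GeneVim(gene, {f: 0.0 for f in FACTORS}, constant=True, params=hp)
    reg = _make_regressor(hp, seed)
    reg.fit(X, y, feature_name=names)
    gains = reg.booster_.feature_importance(importance_type="gain")
    vims = {f: float(gains[idx].sum()) for f, idx in groups.items()}
    return GeneVim(gene, vims, constant=False, params=hp,
                   model=reg.booster_ if keep_model else None,
                   feature_groups=groups if keep_model else None)


def fit_vims(expr: pd.DataFrame, design: SampleDesign,
             hyperparams: Mapping | None = None, seed: int = 0) -> pd.DataFrame:
    """Gene x VIM table for every row of an expression matrix.

    Per-gene seeds are derived deterministically from ``seed`` and the row
    position, so the table is reproducible and independent of chunking.
    """
    rows = {}
    for i, (gene, y) in enumerate(expr.iterrows()):
        gv = fit_gene_vims(y.values, design, hyperparams, seed=seed + i, gene=gene)
        rows[gene] = [gv.vims[f] for f in ("stage", "cultivar", "tissue", "soil")]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(VIM_COLUMNS))


def fit_centroid_vims(clusters: ClusterSet, design: SampleDesign,
                      hyperparams: Mapping | None = None, seed: int = 0) -> pd.DataFrame:
    """Cluster x VIM table fit on centroid profiles instead of member genes.

    Each centroid's condition profile is broadcast to the samples of its
    condition and modeled once per cluster -- a fast alternative to the
    gene-level default when only cluster ranks are needed.
    """
    cond = design.condition_of_samples()
    rows = {}
    for i, cid in enumerate(clusters.centroids.index):
        y = clusters.centroids.loc[cid, cond.values].values
        gv = fit_gene_vims(y, design, hyperparams, seed=seed + i, gene=str(cid))
        rows[cid] = [gv.vims[f] for f in ("stage", "cultivar", "tissue", "soil")]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(VIM_COLUMNS))


@dataclass
class VimTable:
    """Cluster-median VIMs with per-variable ranks (1 = most important)."""

    table: pd.DataFrame  # index cluster id; VIM_* and Rnk_VIM_* columns

    @property
    def k(self) -> int:
        return len(self.table)

    def top_set(self, variable: str, k_top: int) -> set[int]:
        col = f"Rnk_VIM_{variable}"
        return set(self.table.index[self.table[col] <= k_top])


def _dense_rank_desc(values: pd.Series) -> pd.Series:
    """Ranks 1..k, descending by value, ties broken by (cluster) index."""
    order = np.lexsort((values.index.values, -values.values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return pd.Series(ranks, index=values.index)


def cluster_vims(gene_vims: pd.DataFrame, clusters: ClusterSet) -> VimTable:
    """Median member VIM per cluster and variable, plus rank columns."""
    missing = clusters.assignment.index.difference(gene_vims.index)
    if len(missing) == len(clusters.assignment):
        raise ValueError("no clustered gene has a fitted VIM")
    assigned = clusters.assignment.loc[clusters.assignment.index.intersection(gene_vims.index)]
    counts = assigned.value_counts()
    empty = [cid for cid in clusters.centroids.index if counts.get(cid, 0) == 0]
    if empty:
        raise ValueError(f"clusters without modeled genes: {empty}")
    med = gene_vims.loc[assigned.index].groupby(assigned).median()
    med = med.reindex(sorted(clusters.centroids.index))
    for col in VIM_COLUMNS:
        med[f"Rnk_{col}"] = _dense_rank_desc(med[col])
    med.index.name = "cluster"
    return VimTable(med)


@dataclass
class TopKIntersection:
    """Partition of the union of the four per-variable top-k cluster sets."""

    k_top: int
    top_sets: dict[str, set[int]]
    categories: dict[frozenset[str], list[int]]

    def specific(self, variable: str) -> list[int]:
        return self.categories.get(frozenset([variable]), [])

    @property
    def union(self) -> set[int]:
        return set().union(*self.top_sets.values())

    def summary(self) -> pd.DataFrame:
        rows = [{"variables": "&".join(sorted(k)), "n_clusters": len(v),
                 "clusters": v} for k, v in sorted(self.categories.items(),
                                                   key=lambda kv: (len(kv[0]), sorted(kv[0])))]
        return pd.DataFrame(rows)


def top_k_intersections(vim_table: VimTable, k_top: int = 30) -> TopKIntersection:
    """Exact membership partition of the four top-k rank sets.

    Variable-specific clusters appear in exactly one top set; shared
    categories are keyed by the frozenset of variables whose top sets
    contain them.
    """
    if k_top > vim_table.k:
        raise ValueError(f"k_top={k_top} exceeds the number of clusters {vim_table.k}")
    variables = ("stage", "cultivar", "tissue", "soil")
    top_sets = {v: vim_table.top_set(v, k_top) for v in variables}
    categories: dict[frozenset[str], list[int]] = {}
    for cid in sorted(set().union(*top_sets.values())):
        key = frozenset(v for v in variables if cid in top_sets[v])
        categories.setdefault(key, []).append(cid)
    return TopKIntersection(k_top, top_sets, categories)


# ---------------------------------------------------------------------------
# interaction strength


def _partial_dependence(model: lgb.Booster, X: np.ndarray,
                        groups: Mapping[str, Sequence[int]],
                        factors: Sequence[str],
                        level_idx: Sequence[int]) -> float:
    Xm = X.copy()
    for factor, li in zip(factors, level_idx):
        cols = list(groups[factor])
        Xm[:, cols] = 0.0
        Xm[:, cols[li]] = 1.0
    return float(model.predict(Xm).mean())


def pairwise_interaction_strength(gene_vim: GeneVim, design: SampleDesign,
                                  pair: tuple[str, str]) -> float:
    """Friedman's H statistic for one factor pair, in [0, 1].

    H^2 is the share of the joint partial-dependence variance not explained
    by the two one-way partial dependences; H = sqrt(H^2).  Purely additive
    ensembles score near 0.  Requires a fitted model
    (``fit_gene_vims(..., keep_model=True)``).
    """
    if gene_vim.model is None or gene_vim.feature_groups is None:
        raise ValueError("no fitted model attached; fit with keep_model=True")
    f1, f2 = pair
    n1, n2 = len(design.levels[f1]), len(design.levels[f2])
    if n1 < 2 or n2 < 2:
        return 0.0
    X, groups, _ = encode_design(design)
    groups = gene_vim.feature_groups
    pd1 = np.array([_partial_dependence(gene_vim.model, X, groups, [f1], [i])
                    for i in range(n1)])
    pd2 = np.array([_partial_dependence(gene_vim.model, X, groups, [f2], [j])
                    for j in range(n2)])
    pd12 = np.array([[_partial_dependence(gene_vim.model, X, groups, [f1, f2], [i, j])
                      for j in range(n2)] for i in range(n1)])
    # weights: empirical joint frequency of the level pair (uniform under a
    # complete crossing)
    tab = design.table
    w = np.array([[np.mean((tab[f1].values == a) & (tab[f2].values == b))
                   for b in design.levels[f2]] for a in design.levels[f1]])
    w = w / w.sum()
    mean12 = (w * pd12).sum()
    pd1c = pd1 - (w.sum(axis=1) * pd1).sum()
    pd2c = pd2 - (w.sum(axis=0) * pd2).sum()
    joint_c = pd12 - mean12
    resid = joint_c - pd1c[:, None] - pd2c[None, :]
    denom = (w * joint_c ** 2).sum()
    if denom <= 0:
        return 0.0
    h2 = (w * resid ** 2).sum() / denom
    return float(np.sqrt(np.clip(h2, 0.0, 1.0)))


def interaction_matrix(gene_vim: GeneVim, design: SampleDesign) -> pd.DataFrame:
    """H statistic for every factor pair."""
    out = pd.DataFrame(0.0, index=list(FACTORS), columns=list(FACTORS))
    for f1, f2 in itertools.combinations(FACTORS, 2):
        h = pairwise_interaction_strength(gene_vim, design, (f1, f2))
        out.loc[f1, f2] = out.loc[f2, f1] = h
    return out
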