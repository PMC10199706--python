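"""Step 2: co-expression clustering of condition-mean profiles.

Each retained gene is reduced to its average expression per experimental
condition (e.g. 36 cultivar x tissue x stage x soil combinations), the
profile is z-standardized per gene so shape rather than level drives
membership, and k-means groups the profiles.  A cluster is summarized by its
centroid (member mean profile), the share of total profile variance
explained by the partition, and a homogeneity index Rc -- the mean Pearson
correlation between member profiles and the centroid, a scale-free measure
of how representative the average profile is.  k can be chosen as the
smallest grid value whose variance explained reaches a target share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import SampleDesign


@dataclass
class ConditionProfileMatrix:
    """Gene x condition mean-expression profiles."""

    profiles: pd.DataFrame
    standardized: bool = False

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)


def condition_means(expr: pd.DataFrame, design: SampleDesign) -> ConditionProfileMatrix:
    """Average replicate expression per condition, columns in design nesting
    order (cultivar, tissue, stage, soil)."""
    cond = design.condition_of_samples()
    missing = [c for c in design.condition_ids if (cond == c).sum() == 0]
    if missing:
        raise ValueError(f"conditions without samples: {missing[:5]}")
    means = expr.T.groupby(cond.values, observed=False).mean().T
    means = means[design.condition_ids]
    return ConditionProfileMatrix(means, standardized=False)


def standardize_profiles(profiles: ConditionProfileMatrix) -> ConditionProfileMatrix:
    """Per-gene z-standardization; constant profiles are rejected (screen first)."""
    X = profiles.profiles
    sd = X.std(axis=1, ddof=0)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"constant profiles cannot be standardized: "
                         f"{list(flat.index[:5])}")
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    return ConditionProfileMatrix(Z, standardized=True)


@dataclass
class ClusterSet:
    """k-means partition of gene profiles with per-cluster summaries."""

    k: int
    assignment: pd.Series          # gene -> cluster id (1..k)
    centroids: pd.DataFrame        # cluster x condition (member means)
    rc: pd.Series                  # homogeneity index per cluster
    variance_explained: float      # between-cluster SS / total SS
    sizes: pd.Series
    seed: int | None = None

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])


def homogeneity_index(members: pd.DataFrame, centroid: pd.Series) -> float:
    """Mean Pearson correlation between member profiles and the centroid.

    Singleton clusters score 1; zero-variance members are excluded with a
    warning (their correlation is undefined).
    """
    if len(members) == 0:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return 1.0
    c = centroid.values.astype(float)
    c = c - c.mean()
    c_norm = np.sqrt((c ** 2).sum())
    X = members.values.astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    ok = (norms > 0)
    if c_norm == 0:
        return float("nan")
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} zero-variance member(s) excluded from Rc")
    if not ok.any():
        return float("nan")
    r = (Xc[ok] @ c) / (norms[ok] * c_norm)
    return float(r.mean())


def kmeans_clusters(profiles: ConditionProfileMatrix, k: int, seed: int = 0,
                    n_init: int = 25) -> ClusterSet:
    """Best-inertia k-means over ``n_init`` seeded restarts.

    Centroids are recomputed as member means in profile space; variance
    explained is 1 - within-SS / total-SS about the grand centroid.
    """
    X = profiles.profiles
    if k >= len(X):
        raise ValueError("k must be smaller than the number of genes")
    if k < 1:
        raise ValueError("k must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-cluster convergence handled below
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X.values)
    if len(np.unique(labels)) < k:
        raise ValueError(f"empty cluster persists over {n_init} restarts at "
                         f"k={k}; fewer than k distinct profiles")
    assignment = pd.Series(labels + 1, index=X.index, name="cluster")
    centroids = X.groupby(assignment).mean()
    centroids.index.name = "cluster"
    total_ss = float(((X.values - X.values.mean(axis=0)) ** 2).sum())
    within = 0.0
    rc = {}
    sizes = assignment.value_counts().sort_index()
    for cid in centroids.index:
        members = X.loc[assignment == cid]
        within += float(((members.values - centroids.loc[cid].values) ** 2).sum())
        rc[cid] = homogeneity_index(members, centroids.loc[cid])
    ve = 0.0 if total_ss == 0 else 1.0 - within / total_ss
    return ClusterSet(k=k, assignment=assignment, centroids=centroids,
                      rc=pd.Series(rc, name="Rc"),
                      variance_explained=float(ve), sizes=sizes, seed=seed)


def choose_k(profiles: ConditionProfileMatrix, k_grid: Sequence[int],
             target_variance: float = 0.80, seed: int = 0, n_init: int = 25,
             return_curve: bool = False):
    """Smallest k on the grid whose variance explained reaches the target.

    If no grid value reaches the target, the largest k is returned with a
    warning.  With ``return_curve=True`` also returns the k -> variance
    explained series.
    """
    grid = sorted(set(int(k) for k in k_grid))
    if not grid:
        raise ValueError("empty k grid")
    curve = {}
    chosen = None
    for k in grid:
        try:
            ve = kmeans_clusters(profiles, k, seed=seed, n_init=n_init).variance_explained
        except ValueError as err:
            if "empty cluster" not in str(err):
                raise
            warnings.warn(f"k={k} skipped: {err}")
            curve[k] = float("nan")
            continue
        curve[k] = ve
        if chosen is None and ve >= target_variance:
            chosen = k
            if not return_curve:
                break
    if chosen is None:
        valid = [k for k in grid if k in curve and np.isfinite(curve[k])]
        if not valid:
            raise ValueError("no feasible k on the grid")
        chosen = valid[-1]
        warnings.warn(f"no k on the grid reaches variance target "
                      f"{target_variance:.2f}; using k={chosen}")
    series = pd.Series(curve, name="variance_explained")
    return (chosen, series) if return_curve else chosen
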