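"""PCA of samples and of cluster profiles, crossed with VIM ranks.

Two projections are used: (i) a PCA of the variance-stabilized sample
matrix, whose leading components typically separate samples by the dominant
design factors (tissue, then stage); (ii) a PCA of the condition x cluster
matrix of average cluster profiles.  Each design variable is then associated
with the principal component whose cluster loadings track that variable's
cluster VIMs most closely, measured by |Spearman rho| between |loading| and
VIM -- a scale-free realization of "crossing" importance scores with
component structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import SampleDesign
from .importance import VimTable


@dataclass
class PcaResult:
    """Scores (observation x component), loadings (feature x component) and
    per-component variance ratios; deterministic up to the sign convention
    that each loading vector's largest-magnitude entry is positive."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    mean: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _pca(X: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    values = X.values.astype(float)
    if np.ptp(values) == 0:
        raise ValueError("constant matrix has no principal components")
    mean = values.mean(axis=0)
    C = values - mean
    U, S, Vt = np.linalg.svd(C, full_matrices=False)
    # sign convention: largest-|entry| of each loading vector positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = S ** 2
    ratio = var / var.sum()
    k = n_components or min(X.shape[0], X.shape[1])
    k = min(k, len(S))
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * S[:k], index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt[:k].T, index=X.columns, columns=comp)
    return PcaResult(scores, loadings, ratio[:k], pd.Series(mean, index=X.columns))


def sample_pca(expr: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA with samples as observations and genes as features (genes are
    mean-centered internally)."""
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    return _pca(expr.T, n_components)


def cluster_profile_pca(centroids: pd.DataFrame,
                        n_components: int | None = None) -> PcaResult:
    """PCA of average cluster profiles: conditions as observations, clusters
    as features (columns = clusters, as in a condition x cluster matrix)."""
    X = centroids.T if centroids.index.name == "cluster" else centroids
    return _pca(X, n_components)


@dataclass
class ComponentAssociation:
    """variable -> (best component, |Spearman rho| between |loading| and VIM)."""

    table: pd.DataFrame  # index variable; columns component, rho

    def component_of(self, variable: str) -> str:
        return str(self.table.loc[variable, "component"])


def associate_components(pca: PcaResult, vim_table: VimTable) -> ComponentAssociation:
    """For each design variable, the component whose |loadings| correlate
    best (Spearman) with the cluster VIMs of that variable."""
    loadings = pca.loadings
    clusters = vim_table.table.index
    if len(clusters) < 3:
        raise ValueError("component association needs at least 3 clusters")
    if not set(clusters) <= set(loadings.index):
        raise ValueError("cluster ids of the VIM table not found among PCA features")
    L = loadings.loc[clusters].abs()
    rows = {}
    for variable in ("stage", "cultivar", "tissue", "soil"):
        vims = vim_table.table[f"VIM_{variable}"].values
        best_comp, best_rho = None, -1.0
        for comp in L.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # constant VIMs: rho undefined -> 0
                rho = spearmanr(L[comp].values, vims).statistic
            rho = 0.0 if np.isnan(rho) else abs(float(rho))
            if rho > best_rho:
                best_comp, best_rho = comp, rho
        rows[variable] = {"component": best_comp, "rho": best_rho}
    return ComponentAssociation(pd.DataFrame.from_dict(rows, orient="index"))


def plot_scores(pca: PcaResult, design: SampleDesign, factor: str, path,
                components: tuple[str, str] = ("PC1", "PC2")) -> None:
    """Scatter of sample scores colored by a design factor (PNG/SVG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cx, cy = components
    fig, ax = plt.subplots(figsize=(5, 4))
    for level in design.levels[factor]:
        idx = design.table.index[design.table[factor] == level]
        sub = pca.scores.loc[idx]
        ax.scatter(sub[cx], sub[cy], s=18, label=level, alpha=0.8)
    ix, iy = int(cx[2:]) - 1, int(cy[2:]) - 1
    ax.set_xlabel(f"{cx} ({100 * pca.variance_ratio[ix]:.0f}%)")
    ax.set_ylabel(f"{cy} ({100 * pca.variance_ratio[iy]:.0f}%)")
    ax.legend(title=factor, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
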