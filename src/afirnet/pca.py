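"""PCA over the node x ten-metric matrix and confidence-ellipse outliers.

The ten topological metrics live on wildly different scales (stress is an
unbounded count, closeness sits in [0, 1]), so the default analysis is a
correlation-matrix PCA: each column is centered and scaled to unit variance
before the eigendecomposition.  Nodes whose (PC1, PC2) scores fall outside
the chi-square confidence ellipse of the score cloud are flagged as
topological outliers — the molecules whose combination of centralities sets
them apart from the bulk of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .netio import MolecularNetwork
from .topology import METRIC_COLUMNS

logger = logging.getLogger("afirnet")


@dataclass
class FeatureMatrix:
    """Node x metric matrix restricted to the largest connected component."""

    data: pd.DataFrame
    constant_columns: list[str]
    column_means: pd.Series = field(init=False)
    column_sds: pd.Series = field(init=False)

    def __post_init__(self):
        self.column_means = self.data.mean()
        self.column_sds = self.data.std(ddof=1)


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance fractions of a PCA run."""

    loadings: pd.DataFrame  #: metric x component
    scores: pd.DataFrame  #: node x component
    explained_variance_ratio: np.ndarray
    standardized: bool
    dropped_columns: list[str]

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def build_feature_matrix(
    metrics: pd.DataFrame, net: MolecularNetwork | None = None
) -> FeatureMatrix:
    """Select the PCA rows and flag zero-variance columns.

    Rows are the nodes of the largest connected component when the network
    is supplied (metrics of unreachable fragments would mix incompatible
    path-length scales); constant columns are retained in the matrix but
    recorded so the decomposition can drop them.
    """
    data = metrics[METRIC_COLUMNS].copy()
    if net is not None:
        comps = sorted(nx.connected_components(net.graph), key=len, reverse=True)
        if len(comps) > 1:
            keep = [n for n in data.index if n in comps[0]]
            logger.info(
                "feature matrix restricted to largest component: %d of %d nodes",
                len(keep), len(data),
            )
            data = data.loc[keep]
    constant = [c for c in data.columns if data[c].nunique() <= 1]
    if constant:
        logger.warning("constant metric columns: %s", constant)
    return FeatureMatrix(data=data, constant_columns=constant)


def run_pca(fm: FeatureMatrix, standardize: bool = True) -> PCAResult:
    """Eigendecomposition of the (by default) correlation matrix.

    Constant columns are dropped (they are degenerate under standardization).
    Component signs follow a deterministic convention: the largest-magnitude
    loading of each component is made positive.
    """
    data = fm.data.drop(columns=fm.constant_columns)
    if data.shape[0] < 3:
        raise ValueError("PCA needs at least three rows")
    if data.shape[1] < 2:
        raise ValueError("PCA needs at least two non-constant columns")
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        x = x / x.std(axis=0, ddof=1)
    model = PCA(n_components=min(x.shape))
    scores = model.fit_transform(x)
    loadings = model.components_.T  # metric x component
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=data.columns, columns=names),
        scores=pd.DataFrame(scores, index=data.index, columns=names),
        explained_variance_ratio=model.explained_variance_ratio_,
        standardized=standardize,
        dropped_columns=list(fm.constant_columns),
    )


def flag_outliers(result: PCAResult, confidence: float = 0.95) -> pd.Series:
    """Nodes outside the chi-square confidence ellipse of the PC1-PC2 scores.

    The squared Mahalanobis distance of each node's (PC1, PC2) score from
    the score centroid, under the score covariance, is compared against the
    chi-square quantile with two degrees of freedom; a distance beyond the
    quantile puts the node outside the ellipse.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    s = result.scores.iloc[:, :2].to_numpy(dtype=float)
    centered = s - s.mean(axis=0)
    cov = np.cov(centered, rowvar=False, ddof=1)
    inv = np.linalg.pinv(np.atleast_2d(cov))
    d2 = np.einsum("ij,jk,ik->i", centered, inv, centered)
    cutoff = chi2.ppf(confidence, df=2)
    return pd.Series(d2 > cutoff, index=result.scores.index, name="outlier")


def plot_biplot(result: PCAResult, flags: pd.Series | None = None, path=None):
    """PC1-PC2 biplot with the confidence ellipse; optional file output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = result.scores
    fig, ax = plt.subplots(figsize=(7, 6))
    colors = (
        flags.reindex(s.index).map({True: "crimson", False: "steelblue"})
        if flags is not None
        else "steelblue"
    )
    ax.scatter(s["PC1"], s["PC2"], s=18, c=colors, alpha=0.8)
    if flags is not None:
        for n in flags[flags].index:
            ax.annotate(n, (s.loc[n, "PC1"], s.loc[n, "PC2"]), fontsize=7)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.1%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.1%})")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
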