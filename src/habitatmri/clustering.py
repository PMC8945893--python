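"""Hierarchical clustering of radiomic feature tables for heatmap display.

Columns are z-scored (zero-variance columns dropped), rows and columns are
ordered by average-linkage Euclidean dendrograms, and the row dendrogram is
cut into exactly ``n_clusters`` flat clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator


class FeatureHeatmapCluster(BaseEstimator):
    """Agglomerative (average linkage, Euclidean) clustering of feature rows.

    Parameters
    ----------
    n_clusters : int
        Number of flat clusters to cut from the row dendrogram.

    Attributes (after :meth:`fit`)
    ------------------------------
    labels_ : ndarray of int
        Flat cluster id per row (0-based, in input row order).
    row_order_, col_order_ : ndarray of int
        Dendrogram leaf orders for heatmap display.
    zscored_ : DataFrame
        Column-z-scored matrix (zero-variance columns removed).
    row_linkage_, col_linkage_ : ndarray
        scipy linkage matrices.
    """

    def __init__(self, n_clusters: int = 5):
        self.n_clusters = n_clusters

    def fit(self, X: pd.DataFrame | np.ndarray, y=None):
        X = pd.DataFrame(X)
        sd = X.std(ddof=0)
        X = X.loc[:, sd > 0]
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"need at least n_clusters={self.n_clusters} rows, got {X.shape[0]}"
            )
        if X.shape[1] == 0:
            raise ValueError("all columns have zero variance")
        Z = (X - X.mean()) / X.std(ddof=0)
        self.zscored_ = Z
        self.row_linkage_ = hierarchy.linkage(Z.to_numpy(), method="average", metric="euclidean")
        self.row_order_ = hierarchy.leaves_list(self.row_linkage_)
        if Z.shape[1] > 1:
            self.col_linkage_ = hierarchy.linkage(
                Z.to_numpy().T, method="average", metric="euclidean"
            )
            self.col_order_ = hierarchy.leaves_list(self.col_linkage_)
        else:
            self.col_linkage_ = None
            self.col_order_ = np.array([0])
        raw = hierarchy.fcluster(self.row_linkage_, t=self.n_clusters, criterion="maxclust")
        # renumber clusters by first appearance for a stable, order-insensitive id map
        self.labels_ = _canonical_labels(raw)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def cluster_feature_heatmap(table: pd.DataFrame, k: int = 5):
    """Functional wrapper: returns (row_order, col_order, labels, zscored)."""
    model = FeatureHeatmapCluster(n_clusters=k).fit(table)
    return model.row_order_, model.col_order_, model.labels_, model.zscored_


def save_heatmap_png(model: FeatureHeatmapCluster, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Z = model.zscored_.to_numpy()[np.ix_(model.row_order_, model.col_order_)]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(Z, aspect="auto", cmap="vlag" if "vlag" in plt.colormaps() else "coolwarm")
    fig.colorbar(im, ax=ax, label="z-score")
    ax.set_xlabel("features (dendrogram order)")
    ax.set_ylabel("regions (dendrogram order)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
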