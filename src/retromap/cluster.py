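"""Hierarchical clustering of experiments on response profiles.

Experiments are compared by the Pearson correlation of their per-gene
log2 fold-change profiles over the pooled responsive gene set (distance
1 - r) and joined by average linkage (UPGMA), mirroring the
MeV-style tree of perturbation experiments. Genes filtered by the
absent-call rule contribute log2 fold change 0 (fold change 1), so every
experiment shares a complete feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin


def pearson_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson correlation between profile rows.

    ``profiles`` is items x features. Symmetric, zero diagonal, values in
    [0, 2]. A zero-variance profile has no defined correlation and raises,
    naming the offending item.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two items to compute distances")
    x = profiles.to_numpy(float)
    sd = x.std(axis=1)
    flat = profiles.index[sd == 0].tolist()
    if flat:
        raise ValueError(f"zero-variance profile(s): {flat}")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class Dendrogram:
    """Binary merge tree from agglomerative clustering.

    ``linkage`` is a scipy linkage matrix; ``labels`` the leaf names in
    input order. Merge heights are the average-linkage distances.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..k) from cutting the tree at k clusters."""
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")


def average_linkage(distance: pd.DataFrame) -> Dendrogram:
    """UPGMA tree from a symmetric distance matrix.

    Deterministic for a given input order; scipy breaks ties in minimal
    distance by the lowest pair index.
    """
    d = distance.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(z, [str(x) for x in distance.index])


def _quote(name: str) -> str:
    if any(c in name for c in " ()[]:;,'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Dendrogram, precision: int = 10) -> str:
    """Serialize the dendrogram as a Newick string.

    Node depth equals the merge height; a branch length is the difference
    between the parent's and the child's height (leaves sit at height 0),
    so two leaves merging at height h serialize as ``(A:h,B:h);``.
    """
    root, _ = hierarchy.to_tree(tree.linkage, rd=True)

    def fmt(x: float) -> str:
        s = f"{x:.{precision}g}"
        return s

    def rec(node) -> tuple[str, float]:
        if node.is_leaf():
            return _quote(tree.labels[node.id]), 0.0
        left, lh = rec(node.left)
        right, rh = rec(node.right)
        h = float(node.dist)
        return f"({left}:{fmt(h - lh)},{right}:{fmt(h - rh)})", h

    body, _ = rec(root)
    return body + ";"


class ExperimentClusterer(BaseEstimator, ClusterMixin):
    """Average-linkage clustering of experiments under Pearson distance.

    A small sklearn-style wrapper: ``fit`` computes the distance matrix,
    the UPGMA tree and flat labels at ``n_clusters``.

    Attributes
    ----------
    distance_ : DataFrame of pairwise 1 - r distances
    dendrogram_ : fitted :class:`Dendrogram`
    labels_ : flat cluster assignment (ints starting at 1)
    newick_ : Newick serialization of the tree
    """

    def __init__(self, n_clusters: int = 3):
        self.n_clusters = n_clusters

    def fit(self, X: pd.DataFrame, y=None) -> "ExperimentClusterer":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        self.distance_ = pearson_distance(X)
        self.dendrogram_ = average_linkage(self.distance_)
        self.labels_ = self.dendrogram_.cut(self.n_clusters).to_numpy()
        self.newick_ = to_newick(self.dendrogram_)
        return self
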