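"""Global transcriptome similarity: distances, UPGMA, Newick export.

Samples are compared on raw (unscaled) log-expression columns under two
metrics: plain Euclidean distance, which separates profiles by absolute
expression differences, and 1 - Pearson correlation, which groups
profiles that follow the same trend regardless of offset or scale.  The
two views are deliberately complementary: two samples whose profiles are
an affine transform of one another are identical under the correlation
metric yet far apart under the Euclidean one.

Agglomeration is average linkage (UPGMA) via scipy; the dendrogram can
be exported as Newick with ultrametric branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

__all__ = [
    "Dendrogram",
    "TranscriptomeClustering",
    "distance_matrix",
    "average_linkage",
    "export_newick",
]

METRICS = ("euclidean", "one_minus_pearson")


def distance_matrix(values: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix on the columns of ``values``.

    ``one_minus_pearson`` distances lie in [0, 2]; a zero-variance sample
    is rejected by name because its correlation is undefined.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = values.to_numpy(dtype=float)
    cols = values.columns
    if metric == "euclidean":
        diff = arr[:, :, None] - arr[:, None, :]
        d = np.sqrt((diff**2).sum(axis=0))
    else:
        sd = arr.std(axis=0)
        flat = cols[sd == 0]
        if len(flat):
            raise ValueError(f"zero-variance sample(s) under pearson: {list(flat)}")
        d = 1.0 - np.corrcoef(arr, rowvar=False)
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=cols, columns=cols)


@dataclass
class Dendrogram:
    """A UPGMA merge tree over samples.

    ``linkage`` is the scipy linkage matrix (n-1 merges); merge heights
    are non-decreasing because average linkage is monotone.
    """

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows for n leaves")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)


def average_linkage(dist: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix."""
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    z = hierarchy.linkage(squareform(arr, checks=False), method="average")
    return Dendrogram(z, [str(c) for c in dist.columns])


def export_newick(d: Dendrogram) -> str:
    """Newick text with ultrametric branch lengths.

    A node merged at height h sits at depth h/2 from the leaves, so a
    child's branch length is parent depth minus child depth.
    """
    tree = hierarchy.to_tree(d.linkage)

    def walk(node) -> str:
        depth = node.dist / 2.0
        if node.is_leaf():
            return f"{d.labels[node.id]}"
        parts = []
        for child in (node.left, node.right):
            length = depth - child.dist / 2.0
            parts.append(f"{walk(child)}:{length:.10g}")
        return f"({','.join(parts)})"

    return walk(tree) + ";"


class TranscriptomeClustering(BaseEstimator):
    """Average-linkage sample clustering as a scikit-learn estimator.

    ``fit(X)`` takes X of shape (n_samples, n_genes) — a DataFrame index
    provides sample labels.  Fitted attributes: ``distance_matrix_``,
    ``dendrogram_``, ``linkage_``, ``newick_``.
    """

    def __init__(self, metric: str = "euclidean"):
        self.metric = metric

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            values = X.T
        else:
            arr = np.asarray(X, dtype=float)
            values = pd.DataFrame(arr.T, columns=[f"s{i}" for i in range(arr.shape[0])])
        self.distance_matrix_ = distance_matrix(values, self.metric)
        self.dendrogram_ = average_linkage(self.distance_matrix_)
        self.linkage_ = self.dendrogram_.linkage
        self.newick_ = export_newick(self.dendrogram_)
        return self
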