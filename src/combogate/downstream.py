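"""Sample classification on the population matrix.

Mirrors the standard post-enumeration workflow: autoscale each population
column to z-scores, then ordinate samples by PCA and cluster them
hierarchically.  The default distance is one minus the Pearson correlation
between sample profiles with average linkage; Euclidean distance and
complete/Ward linkage are offered as variants.  A separation score counts
how many samples end up in a cluster whose majority label differs from
their own -- the operational form of "the clustering separated the groups".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError

__all__ = [
    "ScaledMatrix",
    "ClusterResult",
    "PCAResult",
    "autoscale",
    "pearson_distance",
    "hcluster",
    "cut_labels",
    "pca",
    "separation_score",
    "to_newick",
]

METRICS = ("pearson", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class ScaledMatrix:
    """Samples x populations z-score matrix.

    Retained columns are centered to mean 0 and scaled to unit sample
    standard deviation (n-1 denominator).  Zero-variance columns carry no
    information for correlation or clustering; they are set to all-zeros
    and listed in ``constant_columns``.
    """

    data: pd.DataFrame
    constant_columns: List[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def autoscale(matrix: pd.DataFrame) -> ScaledMatrix:
    """Column-wise z-scores of a samples x populations matrix."""
    if len(matrix) < 2:
        raise ValidationError(
            f"autoscaling needs >= 2 samples, got {len(matrix)}"
        )
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    constant = sds == 0.0
    scaled = np.zeros_like(values)
    np.divide(values - means, sds, out=scaled, where=~constant)
    scaled[:, constant] = 0.0
    return ScaledMatrix(
        pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns),
        constant_columns=list(matrix.columns[constant]),
    )


def pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - Pearson correlation, in [0, 2].

    A constant vector has no defined correlation; its correlation is taken
    as 0 (distance 1) with a warning, rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError(
            f"need equal-length 1-d vectors of length >= 2, got "
            f"{x.shape} and {y.shape}"
        )
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        warnings.warn(
            "constant vector in correlation distance; treating r as 0",
            stacklevel=2,
        )
        return 1.0
    r = float(xc @ yc / (nx * ny))
    return 1.0 - max(-1.0, min(1.0, r))


def _pairwise_distances(values: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance vector between sample rows."""
    if metric == "euclidean":
        return pdist(values, metric="euclidean")
    n = len(values)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            out[k] = pearson_distance(values[i], values[j])
            k += 1
    return out


@dataclass
class ClusterResult:
    """Hierarchical clustering of samples: scipy linkage matrix + options."""

    linkage_matrix: np.ndarray
    sample_ids: List[str]
    metric: str
    linkage: str

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def hcluster(
    matrix: ScaledMatrix | pd.DataFrame,
    metric: str = "pearson",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of samples on their population profiles.

    Deterministic for a given input: scipy breaks distance ties by cluster
    index, and sample order is preserved from the matrix.
    """
    if metric not in METRICS:
        raise ValidationError(
            f"unknown metric {metric!r}; valid options: {', '.join(METRICS)}"
        )
    if linkage not in LINKAGES:
        raise ValidationError(
            f"unknown linkage {linkage!r}; valid options: {', '.join(LINKAGES)}"
        )
    df = matrix.data if isinstance(matrix, ScaledMatrix) else matrix
    if len(df) < 2:
        raise ValidationError(f"clustering needs >= 2 samples, got {len(df)}")
    dist = _pairwise_distances(df.to_numpy(dtype=float), metric)
    z = hierarchy.linkage(dist, method=linkage)
    return ClusterResult(z, [str(i) for i in df.index], metric, linkage)


def cut_labels(result: ClusterResult, k: int) -> np.ndarray:
    """Flat cluster assignment (1..k) per sample at a k-cluster cut."""
    if not 1 <= k <= result.n_samples:
        raise ValidationError(
            f"k must be in [1, {result.n_samples}], got {k}"
        )
    return hierarchy.fcluster(result.linkage_matrix, t=k, criterion="maxclust")


def separation_score(
    result: ClusterResult, true_labels: Sequence, k: int
) -> int:
    """Misclassified-sample count at a k-cluster cut.

    Each cluster is assigned its majority true label (ties broken by label
    sort order); the score is the number of samples whose own label differs
    from their cluster's majority.  0 means the cut recovers the grouping.
    """
    labels = list(true_labels)
    if len(labels) != result.n_samples:
        raise ValidationError(
            f"{len(labels)} labels for {result.n_samples} samples"
        )
    n_groups = len(set(labels))
    if k < n_groups:
        raise ValidationError(
            f"k = {k} is below the number of true groups ({n_groups})"
        )
    assignment = cut_labels(result, k)
    errors = 0
    for cluster in np.unique(assignment):
        members = [labels[i] for i in np.flatnonzero(assignment == cluster)]
        counts = pd.Series(members).value_counts()
        top = counts.max()
        majority = sorted(counts[counts == top].index)[0]
        errors += sum(lab != majority for lab in members)
    return errors


@dataclass
class PCAResult:
    """Principal components of the scaled matrix (full rank kept)."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # populations x components, orthonormal columns
    variance_explained: np.ndarray  # per-component variance (n-1 denominator)

    @property
    def variance_ratio(self) -> np.ndarray:
        total = self.variance_explained.sum()
        return self.variance_explained / total if total else self.variance_explained


def pca(matrix: ScaledMatrix | pd.DataFrame) -> PCAResult:
    """PCA by SVD of the column-centered matrix.

    Component signs follow a fixed convention -- the largest-magnitude
    loading of each component is made positive -- so results are
    reproducible across runs and BLAS builds.
    """
    df = matrix.data if isinstance(matrix, ScaledMatrix) else matrix
    if len(df) < 2:
        raise ValidationError(f"PCA needs >= 2 samples, got {len(df)}")
    x = df.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    var = s**2 / (len(df) - 1)
    comps = [f"PC{j + 1}" for j in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=df.columns, columns=comps),
        variance_explained=var,
    )


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string with branch lengths.

    Branch lengths are the difference between a node's merge height and its
    parent's, so root-to-leaf path lengths equal merge heights.
    """
    tree = hierarchy.to_tree(result.linkage_matrix)
    ids = result.sample_ids

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
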