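"""Hierarchical clustering of distributions/profiles and dendrogram comparison.

Repertoires (or their diversity profiles) are clustered by complete-linkage
agglomeration on either Euclidean distance (shape *and* magnitude) or
Pearson-correlation distance ``1 - r`` (scale-invariant, shape only).
Agreement between two clusterings of the same samples is measured by the
*cophenetic correlation*: the Pearson correlation between the two trees'
cophenetic distance matrices, where the cophenetic distance of two leaves
is the merge height at which they first join one cluster.  Values near 1
mean the trees tell the same story; values near 0 mean they are unrelated.

The fidelity sweep asks how many alpha values a diversity profile needs
before profile clustering reproduces the clustering of the underlying
clonal frequency distributions, by tracking the cophenetic correlation as
alphas accumulate along the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "CopheneticResult",
    "distance_matrix",
    "hierarchical_cluster",
    "cophenetic_correlation",
    "alpha_sweep",
]

_METRICS = {"euclidean", "pearson_correlation_distance"}


@dataclass(frozen=True)
class DistanceMatrix:
    """Condensed pairwise distances with sample labels."""

    labels: tuple[str, ...]
    condensed: np.ndarray
    metric_tag: str

    @property
    def square(self) -> np.ndarray:
        return squareform(self.condensed)


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree over labelled leaves.

    Wraps a scipy linkage matrix; merge heights are non-decreasing.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray
    linkage_tag: str = "complete"

    def cophenetic_distances(self) -> np.ndarray:
        """Condensed cophenetic distance vector in leaf (label) order."""
        return hierarchy.cophenet(self.linkage)

    def to_newick(self) -> str:
        """Newick export with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height - 0.0:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


@dataclass(frozen=True)
class CopheneticResult:
    """Cophenetic correlation between two dendrograms."""

    r: float
    n_alphas_used: int = 0

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"cophenetic correlation out of range: {self.r}")


def distance_matrix(vectors, labels=None, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between equal-length sample vectors.

    ``pearson_correlation_distance`` is ``1 - r`` (range [0, 2]); vectors
    of zero variance have no defined correlation and raise an error
    naming the offending sample.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 equal-length vectors")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    lab = tuple(str(l) for l in (labels if labels is not None else range(X.shape[0])))
    if len(lab) != X.shape[0]:
        raise ValueError("labels must match number of vectors")
    if metric == "euclidean":
        condensed = pdist(X, metric="euclidean")
    else:
        if X.shape[1] < 2:
            raise ValueError("correlation distance needs vectors of length >= 2")
        sd = X.std(axis=1)
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            raise ValueError(f"zero-variance vector under correlation metric: sample {lab[bad[0]]!r}")
        condensed = pdist(X, metric="correlation")
    return DistanceMatrix(labels=lab, condensed=condensed, metric_tag=metric)


def hierarchical_cluster(dm: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomeration of a distance matrix."""
    if len(dm.labels) < 2:
        raise ValueError("need at least 2 labels to cluster")
    Z = hierarchy.linkage(dm.condensed, method="complete")
    return Dendrogram(labels=dm.labels, linkage=Z)


def cophenetic_correlation(t1: Dendrogram, t2: Dendrogram, n_alphas_used: int = 0) -> CopheneticResult:
    """Pearson correlation of the two trees' cophenetic distance vectors."""
    if set(t1.labels) != set(t2.labels):
        raise ValueError("dendrograms must share one leaf set")
    d1 = t1.cophenetic_distances()
    d2 = t2.cophenetic_distances()
    if t1.labels != t2.labels:
        # re-express t2's condensed vector in t1's label order
        idx = [t2.labels.index(l) for l in t1.labels]
        d2 = squareform(squareform(d2)[np.ix_(idx, idx)])
    r = float(np.corrcoef(d1, d2)[0, 1])
    return CopheneticResult(r=r, n_alphas_used=n_alphas_used)


def _sweep_tree(M: np.ndarray, labels, metric: str) -> Dendrogram:
    if metric == "correlation_matrix_euclidean":
        # correlation-based clustering as rendered by R heatmap pipelines:
        # complete-linkage/Euclidean agglomeration applied to the rows of
        # the sample-sample Pearson correlation matrix
        C = np.corrcoef(M)
        return hierarchical_cluster(distance_matrix(C, labels, metric="euclidean"))
    return hierarchical_cluster(distance_matrix(M, labels, metric=metric))


def alpha_sweep(
    distribution_vectors,
    profile_matrix,
    n_alpha_list,
    labels=None,
    metric: str = "correlation_matrix_euclidean",
    subset_mode: str = "accumulate",
) -> list[CopheneticResult]:
    """Cophenetic fidelity of profile clustering vs distribution clustering.

    Parameters
    ----------
    distribution_vectors
        Equal-composition frequency matrix (samples x clones); clustered
        once as the reference dendrogram.
    profile_matrix
        Diversity-profile matrix (samples x alphas) on one alpha grid.
    n_alpha_list
        Numbers of alpha values to use for the profile dendrogram.
    metric
        ``"correlation_matrix_euclidean"`` (default) applies the
        complete-linkage/Euclidean algorithm to the rows of the
        sample-sample Pearson correlation matrix — correlation-based,
        scale-invariant clustering as produced by the standard R heatmap
        pipeline; alternatively ``"pearson_correlation_distance"`` (direct
        1 - r distances) or ``"euclidean"``.
    subset_mode
        ``"accumulate"`` takes the first n grid alphas (from alpha = 0
        upward); ``"spread"`` takes n evenly spaced alphas across the grid.
    """
    X = np.asarray(distribution_vectors, dtype=float)
    P = np.asarray(profile_matrix, dtype=float)
    if X.shape[0] != P.shape[0]:
        raise ValueError("distribution and profile matrices must share samples")
    if subset_mode not in {"accumulate", "spread"}:
        raise ValueError(f"unknown subset_mode {subset_mode!r}")
    if metric not in _METRICS | {"correlation_matrix_euclidean"}:
        raise ValueError(f"unknown metric {metric!r}")
    lab = labels if labels is not None else [str(i) for i in range(X.shape[0])]
    ref = _sweep_tree(X, lab, metric)
    results = []
    for n in n_alpha_list:
        n = int(n)
        if n < 2 or n > P.shape[1]:
            raise ValueError(f"number of alphas must be in [2, {P.shape[1]}], got {n}")
        if subset_mode == "accumulate":
            cols = np.arange(n)
        else:
            cols = np.unique(np.round(np.linspace(0, P.shape[1] - 1, n)).astype(int))
        tree = _sweep_tree(P[:, cols], lab, metric)
        results.append(cophenetic_correlation(ref, tree, n_alphas_used=n))
    return results
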