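"""Non-supervised suite: hierarchical clustering, k-means, DBSCAN, PCA.

All methods operate on a (normally standardised) :class:`FeatureMatrix` and
return small serialisable report objects. Conventions:

* hierarchical clustering uses Euclidean distance and, by default, average
  linkage; the full merge tree is reported and can be cut at a height or a
  cluster count;
* k-means reports the between_SS/total_SS ratio (fraction of the total sum
  of squares about the grand centroid explained by the cluster centroids)
  and uses k-means++ seeding with multiple restarts;
* DBSCAN labels non-core, non-reachable points as noise (cluster id -1) and
  is made row-order independent by clustering a canonically sorted copy of
  the data;
* PCA reports per-component explained-variance fractions of the
  column-centred matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA

from .features import FeatureMatrix

NOISE = -1


@dataclass
class ClusteringReport:
    method: str
    params: dict
    assignments: np.ndarray  # cluster id per sample; NOISE for DBSCAN outliers
    sizes: dict[int, int]
    between_total_ratio: float | None = None  # k-means only
    merge_tree: np.ndarray | None = None  # hierarchical only, scipy linkage form
    n_noise: int = 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": self.params,
            "assignments": self.assignments.tolist(),
            "sizes": {str(k): v for k, v in self.sizes.items()},
            "between_total_ratio": self.between_total_ratio,
            "merge_tree": None if self.merge_tree is None else self.merge_tree.tolist(),
            "n_noise": self.n_noise,
        }


@dataclass
class PCAResult:
    loadings: np.ndarray  # features x components
    scores: np.ndarray  # samples x components
    explained_fraction: np.ndarray

    def to_dict(self) -> dict:
        return {"explained_fraction": self.explained_fraction.tolist()}


def _sizes(assignments: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(assignments[assignments != NOISE], return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}


def _total_ss(x: np.ndarray) -> float:
    return float(((x - x.mean(axis=0)) ** 2).sum())


def _within_ss(x: np.ndarray, assignments: np.ndarray) -> float:
    w = 0.0
    for cid in np.unique(assignments):
        pts = x[assignments == cid]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(w)


def hierarchical_cluster(
    matrix: FeatureMatrix, method: str = "average", metric: str = "euclidean"
) -> ClusteringReport:
    """Agglomerative clustering; returns the full (n-1)-merge tree."""
    if matrix.n_samples < 2:
        raise ValueError("hierarchical clustering needs at least 2 samples")
    if method not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {method!r}")
    tree = linkage(matrix.values, method=method, metric=metric)
    return ClusteringReport(
        method="hierarchical",
        params={"linkage": method, "metric": metric},
        assignments=np.zeros(matrix.n_samples, dtype=int),
        sizes={0: matrix.n_samples},
        merge_tree=tree,
    )


def cut_tree(report: ClusteringReport, n_clusters: int | None = None, height: float | None = None) -> np.ndarray:
    """Flat clusters from a hierarchical report, at a count or a height."""
    if report.merge_tree is None:
        raise ValueError("report has no merge tree")
    if (n_clusters is None) == (height is None):
        raise ValueError("give exactly one of n_clusters or height")
    if n_clusters is not None:
        return fcluster(report.merge_tree, t=n_clusters, criterion="maxclust") - 1
    return fcluster(report.merge_tree, t=height, criterion="distance") - 1


def kmeans_cluster(
    matrix: FeatureMatrix, k: int, restarts: int = 25, seed: int = 0
) -> ClusteringReport:
    """Best-of-restarts k-means with the between_SS/total_SS quality ratio."""
    n = matrix.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if n == 0 or matrix.n_features == 0:
        raise ValueError("empty matrix")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    assignments = km.fit_predict(matrix.values)
    total = _total_ss(matrix.values)
    within = _within_ss(matrix.values, assignments)
    ratio = 0.0 if total == 0 else 1.0 - within / total
    return ClusteringReport(
        method="kmeans",
        params={"k": k, "restarts": restarts, "seed": seed},
        assignments=assignments,
        sizes=_sizes(assignments),
        between_total_ratio=ratio,
    )


def within_ss_curve(matrix: FeatureMatrix, k_max: int, restarts: int = 10, seed: int = 0) -> np.ndarray:
    """Total within-cluster SS for k = 1 .. k_max."""
    if k_max > matrix.n_samples:
        raise ValueError("k_max exceeds the sample count")
    curve = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        assignments = km.fit_predict(matrix.values)
        curve.append(_within_ss(matrix.values, assignments))
    return np.array(curve)


def elbow_select_k(matrix: FeatureMatrix, k_max: int, restarts: int = 10, seed: int = 0) -> int:
    """Elbow selection: k maximising the perpendicular distance between the
    within-SS curve and the chord joining its endpoints; ties break toward
    the smallest k (a perfectly linear curve has no elbow and yields k=1).
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    curve = within_ss_curve(matrix, k_max, restarts=restarts, seed=seed)
    ks = np.arange(1, k_max + 1, dtype=float)
    p0 = np.array([ks[0], curve[0]])
    p1 = np.array([ks[-1], curve[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 1
    pts = np.column_stack([ks, curve]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(ks[int(np.argmax(np.round(dist, 12)))])


def dbscan_cluster(matrix: FeatureMatrix, eps: float, min_pts: int) -> ClusteringReport:
    """Density-based clustering; unreachable points are labelled noise.

    Rows are canonically sorted before clustering so that the border-point
    assignment (first claiming core cluster in neighbour order) does not
    depend on the input row order.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be at least 1")
    if matrix.n_samples == 0:
        raise ValueError("empty matrix")
    order = np.lexsort(matrix.values.T[::-1])
    labels_sorted = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(matrix.values[order])
    assignments = np.empty(matrix.n_samples, dtype=int)
    assignments[order] = labels_sorted
    n_noise = int((assignments == NOISE).sum())
    return ClusteringReport(
        method="dbscan",
        params={"eps": eps, "min_pts": min_pts},
        assignments=assignments,
        sizes=_sizes(assignments),
        n_noise=n_noise,
    )


def pca_decompose(matrix: FeatureMatrix, n_components: int) -> PCAResult:
    """PCA of the column-centred matrix, components by decreasing variance."""
    bound = min(matrix.n_samples - 1, matrix.n_features)
    if not 1 <= n_components <= bound:
        raise ValueError(f"n_components must be in [1, {bound}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    return PCAResult(
        loadings=pca.components_.T,
        scores=scores,
        explained_fraction=pca.explained_variance_ratio_,
    )
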