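"""Clustering and PCA checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from honeychem.unsupervised import (
    cut_tree,
    dbscan_cluster,
    elbow_select_k,
    hierarchical_cluster,
    kmeans_cluster,
    pca_decompose,
)

from conftest import matrix_from_values


# -- oracles ------------------------------------------------------------------


def brute_force_average_linkage(points):
    """Agglomerate by the smallest mean pairwise inter-cluster distance,
    recomputed from scratch at every step."""
    points = np.asarray(points, dtype=float)
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [np.linalg.norm(points[i] - points[j]) for i in clusters[a] for j in clusters[b]]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def brute_force_min_within_ss_2_partition(points):
    """Minimum within-cluster SS over all 2-partitions, by enumeration."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):
        sel = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        w = 0.0
        for part in (points[sel], points[~sel]):
            if len(part):
                w += ((part - part.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return best


def brute_force_dbscan(points, eps, min_pts):
    """Transitive closure of the core-neighbourhood relation."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbours = [set(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    core = [i for i in range(n) if len(neighbours[i]) >= min_pts]
    labels = {i: None for i in range(n)}
    cid = 0
    for seed in core:
        if labels[seed] is not None:
            continue
        stack, members = [seed], set()
        while stack:
            p = stack.pop()
            if p in members:
                continue
            members.add(p)
            if p in core:
                stack.extend(neighbours[p] - members)
        for p in members:
            if labels[p] is None:
                labels[p] = cid
        cid += 1
    return np.array([-1 if labels[i] is None else labels[i] for i in range(n)])


def same_partition(a, b):
    """Equal clusterings up to relabelling (noise label -1 compared as-is)."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


# -- hierarchical -------------------------------------------------------------


def test_hierarchical_merge_count_and_monotone_heights(std_matrix):
    report = hierarchical_cluster(std_matrix)
    assert report.merge_tree.shape == (67, 4)
    heights = report.merge_tree[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)


def test_hierarchical_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    points = rng.normal(size=(6, 3))
    report = hierarchical_cluster(matrix_from_values(points))
    oracle = brute_force_average_linkage(points)
    np.testing.assert_allclose(report.merge_tree[:, 2], [d for d, _ in oracle], rtol=1e-10)
    np.testing.assert_array_equal(report.merge_tree[:, 3], [s for _, s in oracle])


def test_hierarchical_cut_separates_well_separated_groups():
    rng = np.random.default_rng(0)
    points = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(10, 0.01, (4, 2))])
    report = hierarchical_cluster(matrix_from_values(points))
    flat = cut_tree(report, n_clusters=2)
    assert len(set(flat[:5])) == 1 and len(set(flat[5:])) == 1
    assert flat[0] != flat[-1]


def test_hierarchical_needs_two_samples():
    with pytest.raises(ValueError):
        hierarchical_cluster(matrix_from_values(np.zeros((1, 3))))


# -- k-means ------------------------------------------------------------------


def test_kmeans_matches_exhaustive_2_partition_minimum():
    rng = np.random.default_rng(11)
    points = rng.normal(size=(8, 2))
    matrix = matrix_from_values(points)
    report = kmeans_cluster(matrix, k=2, restarts=25, seed=0)
    total = ((points - points.mean(axis=0)) ** 2).sum()
    within = (1 - report.between_total_ratio) * total
    assert within == pytest.approx(brute_force_min_within_ss_2_partition(points), rel=1e-9)


def test_kmeans_ratio_limits():
    points = np.random.default_rng(2).normal(size=(6, 2))
    matrix = matrix_from_values(points)
    assert kmeans_cluster(matrix, k=1).between_total_ratio == pytest.approx(0.0)
    assert kmeans_cluster(matrix, k=6).between_total_ratio == pytest.approx(1.0)


def test_kmeans_ss_conservation(std_matrix):
    report = kmeans_cluster(std_matrix, k=4, restarts=10, seed=0)
    x = std_matrix.values
    total = ((x - x.mean(axis=0)) ** 2).sum()
    within = sum(
        ((x[report.assignments == c] - x[report.assignments == c].mean(axis=0)) ** 2).sum()
        for c in np.unique(report.assignments)
    )
    assert report.between_total_ratio == pytest.approx(1 - within / total, rel=1e-9)
    assert sum(report.sizes.values()) == std_matrix.n_samples


def test_kmeans_rejects_bad_k(std_matrix):
    with pytest.raises(ValueError):
        kmeans_cluster(std_matrix, k=0)
    with pytest.raises(ValueError):
        kmeans_cluster(std_matrix, k=69)


# -- elbow --------------------------------------------------------------------


def test_elbow_finds_four_well_separated_blobs():
    rng = np.random.default_rng(3)
    centres = np.array([[0, 0], [30, 0], [0, 30], [30, 30]], dtype=float)
    points = np.vstack([c + rng.normal(0, 1.0, (12, 2)) for c in centres])
    assert elbow_select_k(matrix_from_values(points), k_max=8, seed=0) == 4


def test_elbow_linear_curve_ties_to_smallest_k(monkeypatch):
    import honeychem.unsupervised as mod

    monkeypatch.setattr(
        mod, "within_ss_curve", lambda *a, **k: np.array([10.0, 8.0, 6.0, 4.0, 2.0])
    )
    assert mod.elbow_select_k(matrix_from_values(np.zeros((10, 2))), k_max=5) == 1


# -- DBSCAN -------------------------------------------------------------------


def test_dbscan_single_dense_cluster_and_lone_outlier():
    rng = np.random.default_rng(4)
    points = np.vstack([rng.normal(0, 0.05, (8, 2)), [[50.0, 50.0]]])
    report = dbscan_cluster(matrix_from_values(points), eps=1.0, min_pts=3)
    assert len(report.sizes) == 1
    assert report.n_noise == 1
    assert report.assignments[-1] == -1


def test_dbscan_matches_reachability_closure_oracle():
    rng = np.random.default_rng(6)
    points = np.vstack(
        [
            rng.normal(0, 0.3, (5, 2)),
            rng.normal(5, 0.3, (5, 2)),
            [[20.0, 20.0], [-20.0, 0.0]],
        ]
    )
    matrix = matrix_from_values(points)
    report = dbscan_cluster(matrix, eps=1.5, min_pts=3)
    oracle = brute_force_dbscan(points, eps=1.5, min_pts=3)
    assert same_partition(report.assignments, oracle)
    assert report.n_noise == int((oracle == -1).sum())


def test_dbscan_row_order_invariance():
    rng = np.random.default_rng(8)
    points = np.vstack([rng.normal(0, 0.4, (6, 2)), rng.normal(4, 0.4, (6, 2))])
    matrix = matrix_from_values(points)
    base = dbscan_cluster(matrix, eps=1.2, min_pts=3).assignments
    perm = rng.permutation(len(points))
    shuffled = dbscan_cluster(matrix_from_values(points[perm]), eps=1.2, min_pts=3).assignments
    assert same_partition(base[perm], shuffled)


def test_dbscan_validates_parameters(std_matrix):
    with pytest.raises(ValueError):
        dbscan_cluster(std_matrix, eps=0.0, min_pts=3)
    with pytest.raises(ValueError):
        dbscan_cluster(std_matrix, eps=1.0, min_pts=0)


# -- PCA ----------------------------------------------------------------------


def test_pca_variances_match_covariance_eigenvalues():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(5, 4))
    result = pca_decompose(matrix_from_values(x), n_components=4)
    eigvals = np.sort(np.linalg.eigvalsh(np.cov(x.T, ddof=1)))[::-1]
    np.testing.assert_allclose(
        result.explained_fraction, eigvals / eigvals.sum(), rtol=1e-9
    )
    assert np.all(np.diff(result.explained_fraction) <= 1e-12)
    # orthonormal loadings, centred scores
    np.testing.assert_allclose(result.loadings.T @ result.loadings, np.eye(4), atol=1e-9)
    np.testing.assert_allclose(result.scores.mean(axis=0), 0, atol=1e-9)


def test_pca_rank_one_matrix_explained_by_pc1():
    u = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
    result = pca_decompose(matrix_from_values(u), n_components=2)
    assert result.explained_fraction[0] == pytest.approx(1.0)


def test_pca_full_components_reconstruct(std_matrix):
    n = std_matrix.n_samples - 1
    result = pca_decompose(std_matrix, n_components=n)
    assert result.explained_fraction.sum() == pytest.approx(1.0)
    centred = std_matrix.values - std_matrix.values.mean(axis=0)
    np.testing.assert_allclose(result.scores @ result.loadings.T, centred, atol=1e-8)


def test_pca_rejects_excess_components(std_matrix):
    with pytest.raises(ValueError):
        pca_decompose(std_matrix, n_components=68)
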