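"""Point sampling and grouping primitives: farthest point sampling,
k-nearest-neighbour grouping, and multi-scale KNN grouping.

Ball-query grouping makes the neighbourhood size depend on a radius;
for fine filamentous structures a fixed neighbour count is more stable,
so grouping here is KNN-based, and a *multi-scale* group concatenates
several k values per centroid so both fine and coarse context are seen.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _lexicographic_min(points: np.ndarray, candidates: np.ndarray) -> int:
    """Index (into the full array) of the lexicographically smallest
    candidate point; deterministic tie-break independent of input order."""
    sub = points[candidates]
    order = np.lexsort((sub[:, 2], sub[:, 1], sub[:, 0]))
    return int(candidates[order[0]])


def farthest_point_sample(
    points: np.ndarray, n: int, start_index: int | None = None
) -> np.ndarray:
    """Greedy max-min subset selection.

    Starting from ``start_index`` (default: the point farthest from the
    centroid), repeatedly add the point whose distance to the selected
    set is largest.  Ties are broken toward the lexicographically
    smallest coordinates, so the selected *set* does not depend on the
    ordering of the input array.

    Returns ``n`` distinct indices into ``points``.
    """
    points = np.asarray(points, dtype=np.float64)
    count = len(points)
    if not 1 <= n <= count:
        raise ValueError(f"n must be in [1, {count}], got {n}")
    if start_index is None:
        d0 = np.linalg.norm(points - points.mean(axis=0), axis=1)
        cand = np.flatnonzero(d0 == d0.max())
        start_index = _lexicographic_min(points, cand)
    selected = np.empty(n, dtype=np.int64)
    selected[0] = start_index
    min_d2 = np.sum((points - points[start_index]) ** 2, axis=1)
    for i in range(1, n):
        best = min_d2.max()
        cand = np.flatnonzero(min_d2 == best)
        nxt = _lexicographic_min(points, cand)
        selected[i] = nxt
        min_d2 = np.minimum(min_d2, np.sum((points - points[nxt]) ** 2, axis=1))
    return selected


def knn_group(points: np.ndarray, centroid_indices: np.ndarray, k: int) -> np.ndarray:
    """Per-centroid lists of the k nearest point indices (Euclidean;
    the centroid itself is eligible and is its own nearest neighbour).

    If the cloud holds fewer than k points, each list is padded by
    repeating the nearest index so every group has exactly k entries.
    """
    points = np.asarray(points, dtype=np.float64)
    centroid_indices = np.asarray(centroid_indices, dtype=np.int64)
    if len(points) == 0:
        raise ValueError("empty cloud")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, len(points))
    tree = cKDTree(points)
    _, idx = tree.query(points[centroid_indices], k=k_eff)
    idx = np.atleast_2d(idx)
    if idx.shape[0] != len(centroid_indices):  # k_eff == 1 edge shape
        idx = idx.reshape(len(centroid_indices), k_eff)
    if k_eff < k:
        pad = np.repeat(idx[:, :1], k - k_eff, axis=1)
        idx = np.concatenate([idx, pad], axis=1)
    return idx.astype(np.int64)


def multi_scale_group(
    points: np.ndarray,
    features: np.ndarray,
    centroid_indices: np.ndarray,
    k_list: list[int],
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Group features at several KNN scales and concatenate.

    For each ``k`` in ``k_list`` the features of the k nearest
    neighbours of every centroid are gathered and flattened; scales are
    concatenated along the feature axis, giving a constant per-centroid
    width of ``sum(k) * n_features`` that supports batched processing.

    Returns ``(grouped, index_lists)`` where ``grouped`` has shape
    ``(n_centroids, sum(k_list) * n_features)`` and ``index_lists`` are
    the per-scale KNN index arrays.
    """
    features = np.asarray(features, dtype=np.float64)
    if len(features) != len(points):
        raise ValueError("features must be parallel to points")
    if not k_list:
        raise ValueError("k_list must be nonempty")
    blocks = []
    index_lists = []
    for k in k_list:
        idx = knn_group(points, centroid_indices, k)
        index_lists.append(idx)
        blocks.append(features[idx].reshape(len(idx), -1))
    return np.concatenate(blocks, axis=1), index_lists
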