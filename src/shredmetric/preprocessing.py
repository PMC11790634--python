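"""Point-cloud preprocessing: ROI crop, radius filter, Gaussian smoothing,
voxel downsampling.

Raw dual-surface scans are dominated by stage/background returns and
sensor noise.  The standard cleanup chain applied here, in order, is

1. ``crop_roi_by_z``     — keep the z band occupied by the material;
2. ``radius_filter``     — drop isolated returns (density test);
3. ``gaussian_smooth``   — kernel-weighted smoothing of z;
4. ``downsample``        — voxel-grid reduction with majority-label vote.

With the documented defaults the chain reduces a dense scan to roughly a
tenth of its original size while preserving surface structure, which is
what makes network training and measurement tractable.

All four operations are label-preserving on surviving points and never
move a point outside the bounding box of its input neighbourhood.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .io_model import LabeledPointCloud

log = logging.getLogger(__name__)


def crop_roi_by_z(cloud: LabeledPointCloud, z_min: float, z_max: float) -> LabeledPointCloud:
    """Keep exactly the points with ``z_min <= z <= z_max``."""
    if not z_min < z_max:
        raise ValueError("z_min must be < z_max")
    mask = (cloud.points[:, 2] >= z_min) & (cloud.points[:, 2] <= z_max)
    if not mask.any():
        log.warning("crop_roi_by_z removed all %d points", len(cloud))
    return cloud.select(mask)


def radius_filter(
    cloud: LabeledPointCloud, radius: float, min_neighbors: int
) -> LabeledPointCloud:
    """Discard points with fewer than ``min_neighbors`` *other* points
    within ``radius`` (the point itself does not count as its own
    neighbour)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    if len(cloud) == 0:
        return cloud.copy()
    tree = cKDTree(cloud.points)
    counts = tree.query_ball_point(cloud.points, r=radius, return_length=True)
    mask = (counts - 1) >= min_neighbors  # self is always within radius 0
    return cloud.select(mask)


def gaussian_smooth(
    cloud: LabeledPointCloud, sigma: float, radius: float | None = None
) -> LabeledPointCloud:
    """Replace each point's z by the Gaussian-kernel-weighted mean of
    neighbour z values within ``radius`` (default 3·sigma) in the scan
    plane; x, y and labels are unchanged.

    Neighbourhoods are taken in x,y because scans are single-valued
    height fields over the scan grid.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius is None:
        radius = 3.0 * sigma
    if len(cloud) == 0:
        return cloud.copy()
    xy = cloud.points[:, :2]
    z = cloud.points[:, 2]
    tree = cKDTree(xy)
    new_z = np.empty_like(z)
    neighbor_lists = tree.query_ball_point(xy, r=radius)
    for i, idx in enumerate(neighbor_lists):
        idx = np.asarray(idx)
        d2 = np.sum((xy[idx] - xy[i]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma * sigma))
        new_z[i] = np.dot(w, z[idx]) / w.sum()
    pts = cloud.points.copy()
    pts[:, 2] = new_z
    return LabeledPointCloud(pts, cloud.labels.copy(), cloud.surface)


def downsample(cloud: LabeledPointCloud, voxel: float) -> LabeledPointCloud:
    """Voxel-grid downsampling: one representative per occupied voxel,
    placed at the member centroid with the majority label (ties broken
    toward the smallest label code)."""
    if voxel <= 0:
        raise ValueError("voxel must be > 0")
    if len(cloud) == 0:
        return cloud.copy()
    keys = np.floor(cloud.points / voxel).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    n_vox = len(counts)
    centroids = np.zeros((n_vox, 3))
    np.add.at(centroids, inverse, cloud.points)
    centroids /= counts[:, None]
    # majority label per voxel; bincount over (voxel, label) pairs
    pair = inverse * 5 + cloud.labels
    votes = np.bincount(pair, minlength=n_vox * 5).reshape(n_vox, 5)
    labels = np.argmax(votes, axis=1)  # argmax takes the smallest code on ties
    return LabeledPointCloud(centroids, labels, cloud.surface)


def preprocess(
    cloud: LabeledPointCloud,
    z_min: float,
    z_max: float,
    radius: float,
    min_neighbors: int,
    sigma: float,
    voxel: float,
    smooth_radius: float | None = None,
) -> LabeledPointCloud:
    """Full chain: crop → radius filter → Gaussian smooth → downsample."""
    out = crop_roi_by_z(cloud, z_min, z_max)
    out = radius_filter(out, radius, min_neighbors)
    out = gaussian_smooth(out, sigma, smooth_radius)
    out = downsample(out, voxel)
    log.info("preprocess: %d -> %d points (%.1f%%)", len(cloud), len(out),
             100.0 * len(out) / max(len(cloud), 1))
    return out
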