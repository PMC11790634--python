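"""Dual-surface registration via a standard gauge block.

The two surface scans share no overlap (one is taken from above the
transparent stage, one from below), so feature- or ICP-style
registration cannot work.  Instead a precision gauge block
(30 × 9 × 0.5 mm nominal) is scanned together with the material.  Five
reference points are extracted from its footprint on each surface —
the rectangle center, the two length-edge midpoints and the two
width-edge midpoints — and the lower cloud is shifted by the per-axis
mean of the five (upper − lower) differences.  The model is a rigid
translation only; rotational misalignment of the rig is not corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_model import LabeledPointCloud

log = logging.getLogger(__name__)

DEFAULT_GAUGE_THICKNESS = 0.5  # mm
DEFAULT_GAUGE_LENGTH = 30.0
DEFAULT_GAUGE_WIDTH = 9.0


@dataclass
class GaugeReference:
    """Five matched reference point pairs on the gauge block.

    Row order: center, +length edge midpoint, -length edge midpoint,
    +width edge midpoint, -width edge midpoint (axes oriented
    consistently across surfaces).
    """

    upper_points: np.ndarray
    lower_points: np.ndarray
    thickness: float = DEFAULT_GAUGE_THICKNESS
    nominal_length: float = DEFAULT_GAUGE_LENGTH
    nominal_width: float = DEFAULT_GAUGE_WIDTH

    def __post_init__(self) -> None:
        self.upper_points = np.asarray(self.upper_points, dtype=np.float64)
        self.lower_points = np.asarray(self.lower_points, dtype=np.float64)
        if self.upper_points.shape != (5, 3) or self.lower_points.shape != (5, 3):
            raise ValueError("exactly 5 matched (x, y, z) reference pairs required")
        if self.thickness <= 0:
            raise ValueError("gauge thickness must be > 0")

    def mean_offset(self) -> np.ndarray:
        """Per-axis mean of the five upper − lower differences."""
        return (self.upper_points - self.lower_points).mean(axis=0)

    def registered(self) -> "GaugeReference":
        """The same reference expressed after the lower cloud has been
        shifted by :meth:`mean_offset` (for use with registered scenes)."""
        return GaugeReference(
            self.upper_points.copy(),
            self.lower_points + self.mean_offset(),
            self.thickness,
            self.nominal_length,
            self.nominal_width,
        )


def _footprint_references(points: np.ndarray, disk_radius: float) -> np.ndarray:
    """Center and edge midpoints of the oriented bounding rectangle of
    the x,y footprint, each with z = mean surface height within a disk.
    """
    xy = points[:, :2]
    centroid = xy.mean(axis=0)
    centered = xy - centroid
    cov = centered.T @ centered / len(xy)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] < 1e-12 * max(evals[1], 1e-30):
        raise ValueError("degenerate (collinear) gauge footprint")
    u = evecs[:, 1]  # long axis
    v = evecs[:, 0]
    # orient axes deterministically so upper/lower pairs match
    if u[0] < 0 or (abs(u[0]) < 1e-12 and u[1] < 0):
        u = -u
    if u[0] * v[1] - u[1] * v[0] < 0:
        v = -v
    pu = centered @ u
    pv = centered @ v
    cu, cv = (pu.min() + pu.max()) / 2, (pv.min() + pv.max()) / 2
    hu, hv = (pu.max() - pu.min()) / 2, (pv.max() - pv.min()) / 2
    rect_center = centroid + cu * u + cv * v
    refs_xy = np.array(
        [
            rect_center,
            rect_center + hu * u,
            rect_center - hu * u,
            rect_center + hv * v,
            rect_center - hv * v,
        ]
    )
    tree = cKDTree(xy)
    refs = np.empty((5, 3))
    for i, rxy in enumerate(refs_xy):
        idx = tree.query_ball_point(rxy, disk_radius)
        if not idx:
            _, j = tree.query(rxy)
            idx = [int(j)]
        refs[i] = [rxy[0], rxy[1], points[idx, 2].mean()]
    return refs


def extract_reference_points(
    upper_gauge_cloud: LabeledPointCloud | np.ndarray,
    lower_gauge_cloud: LabeledPointCloud | np.ndarray,
    disk_radius: float = 0.15,
    thickness: float = DEFAULT_GAUGE_THICKNESS,
) -> GaugeReference:
    """Build the five matched reference pairs from segmented gauge
    clouds of each surface.

    ``disk_radius`` (mm) sets the neighbourhood used to average the
    surface height at each reference point; the default is three grid
    pitches at the 0.05 mm default pitch.
    """
    up = upper_gauge_cloud.points if isinstance(upper_gauge_cloud, LabeledPointCloud) else np.asarray(upper_gauge_cloud)
    lo = lower_gauge_cloud.points if isinstance(lower_gauge_cloud, LabeledPointCloud) else np.asarray(lower_gauge_cloud)
    if len(up) < 3 or len(lo) < 3:
        raise ValueError("gauge clouds must contain the segmented block")
    return GaugeReference(
        _footprint_references(up, disk_radius),
        _footprint_references(lo, disk_radius),
        thickness=thickness,
    )


def register_lower(
    lower_cloud: LabeledPointCloud, ref: GaugeReference
) -> tuple[LabeledPointCloud, np.ndarray]:
    """Translate the lower-surface cloud into the upper frame.

    Adds the mean per-axis difference over the five reference pairs
    (upper − lower) to every lower point.  Returns the shifted cloud
    and the applied offset.
    """
    offset = ref.mean_offset()
    log.info("registration offset (mm): %s", np.array2string(offset, precision=6))
    return lower_cloud.translated(offset), offset
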