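"""Dataset augmentation for labeled shred clouds.

Four augmentations are provided, mirroring the acquisition rig's
invariances rather than inventing new geometry:

* global random displacement — one uniform (Δx, Δy, Δz) draw per cloud;
* global random rotation     — one uniform angle about a fixed axis
  (Y by default, the scan direction);
* label rotation             — rotate only the points of one shred
  class about that subset's own centroid;
* background removal         — drop every label-4 point.

Displacement and rotation are isometries and all four operations
preserve labels on retained points, so ground truth survives
augmentation unchanged.  Enabling ``k`` methods and pooling with the
originals yields a ``(1 + k)``-fold dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_model import BACKGROUND_LABEL, LabeledPointCloud

log = logging.getLogger(__name__)

_AXES = {"X": 0, "Y": 1, "Z": 2}


@dataclass
class AugmentationSpec:
    """Parameters for the random augmentations.

    displacement_range defaults to [-0.1, 0.1] mm per axis and
    angle_range to [0, 2π]; one draw per cloud, not per point.
    """

    displacement_range: tuple[float, float] = (-0.1, 0.1)
    rotation_axis: str = "Y"
    angle_range: tuple[float, float] = (0.0, 2.0 * math.pi)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.displacement_range
        if lo > hi:
            raise ValueError("displacement_range lo must be <= hi")
        a0, a1 = self.angle_range
        if not (0.0 <= a0 <= a1 <= 2.0 * math.pi + 1e-12):
            raise ValueError("angle_range must lie within [0, 2*pi]")
        if self.rotation_axis not in _AXES:
            raise ValueError("rotation_axis must be one of X, Y, Z")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def rotation_matrix(axis: str, theta: float) -> np.ndarray:
    """3x3 rotation by ``theta`` about the given coordinate axis."""
    c, s = math.cos(theta), math.sin(theta)
    if axis == "X":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=np.float64)
    if axis == "Y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=np.float64)
    if axis == "Z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=np.float64)
    raise ValueError(f"unknown axis {axis!r}")


def global_random_displacement(
    cloud: LabeledPointCloud, spec: AugmentationSpec
) -> LabeledPointCloud:
    """Add one random (Δx, Δy, Δz), each uniform in the configured
    range, to every point; labels unchanged."""
    lo, hi = spec.displacement_range
    delta = spec.rng().uniform(lo, hi, size=3)
    return LabeledPointCloud(cloud.points + delta, cloud.labels.copy(), cloud.surface)


def global_random_rotation(
    cloud: LabeledPointCloud, spec: AugmentationSpec, theta: float | None = None
) -> LabeledPointCloud:
    """Rotate the whole cloud by one random angle about the configured
    axis (through the origin); labels unchanged."""
    if theta is None:
        theta = spec.rng().uniform(*spec.angle_range)
    R = rotation_matrix(spec.rotation_axis, theta)
    return LabeledPointCloud(cloud.points @ R.T, cloud.labels.copy(), cloud.surface)


def label_rotation(
    cloud: LabeledPointCloud,
    target_label: int,
    spec: AugmentationSpec,
    theta: float | None = None,
) -> LabeledPointCloud:
    """Rotate only the points carrying ``target_label`` about the axis
    through that subset's centroid; every other point is untouched.

    Pivoting about the subset centroid keeps the rotated shred inside
    the scene instead of sweeping it around the global origin.
    """
    if target_label not in range(4):
        raise ValueError("target_label must be a shred class (0..3)")
    mask = cloud.labels == target_label
    if not mask.any():
        log.warning("label_rotation: no points with label %d; identity", target_label)
        return cloud.copy()
    if theta is None:
        theta = spec.rng().uniform(*spec.angle_range)
    R = rotation_matrix(spec.rotation_axis, theta)
    pts = cloud.points.copy()
    pivot = pts[mask].mean(axis=0)
    pts[mask] = (pts[mask] - pivot) @ R.T + pivot
    return LabeledPointCloud(pts, cloud.labels.copy(), cloud.surface)


def remove_background(cloud: LabeledPointCloud) -> LabeledPointCloud:
    """Drop every background/noise (label 4) point, order preserved."""
    return cloud.select(cloud.labels != BACKGROUND_LABEL)


_METHODS = {
    "grd": global_random_displacement,
    "grr": global_random_rotation,
    "rbl": lambda cloud, spec: remove_background(cloud),
}


def assemble_augmented_dataset(
    clouds: list[LabeledPointCloud],
    methods: tuple[str, ...] = ("grd", "grr", "rbl"),
    seed: int = 0,
) -> list[LabeledPointCloud]:
    """Pool the originals with one augmented copy per enabled method;
    the result is ``(1 + len(methods))`` times the original size.

    Methods: ``grd`` (global displacement), ``grr`` (global rotation),
    ``rbl`` (remove background label).  Label rotation is available via
    :func:`label_rotation` but is not enabled by default: in practice it
    degrades rather than helps segmentation training.
    """
    unknown = set(methods) - set(_METHODS)
    if unknown:
        raise ValueError(f"unknown augmentation methods: {sorted(unknown)}")
    out = [c.copy() for c in clouds]
    for m_i, name in enumerate(methods):
        fn = _METHODS[name]
        for c_i, cloud in enumerate(clouds):
            spec = AugmentationSpec(rng_seed=seed * 100003 + m_i * 1009 + c_i)
            out.append(fn(cloud, spec))
    return out
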