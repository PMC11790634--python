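"""DTC (dimension transformation calculation): true 3-D length, width
and thickness of segmented filaments.

Curved, twisted filaments make direct 3-D centerline extraction
awkward; the DTC route instead maps 3-D → 2-D → 3-D:

1. project the surface cloud to a 2-D image on the scan grid (height
   mapped to gray; instance masks from the per-point labels);
2. cut the instance mask into horizontal bands, take one center per
   connected run of pixels in each band, and chain the centers by
   greedy nearest-neighbour into a skeleton polyline;
3. lift the 2-D skeleton (and the width-profile points) back to 3-D by
   inverse-distance interpolation of the nearby cloud z;
4. length = polyline arc length in 3-D; width = per-segment
   perpendicular profile through the segment midpoint, intersected with
   the instance contour, both intersections lifted to 3-D; thickness =
   gauge-referenced height differences of the two surfaces.

Thickness uses the registered dual-surface clouds and the reference
gauge block of known thickness H: with H1 the mean upper-surface height
difference between shred and gauge and H2 the lower-surface analogue,
``T = H - H1 - H2`` when the shred's upper surface lies below the
gauge top, else ``T = H + H1 - H2``.

A 2-D projected length (the z term dropped) is kept as the baseline a
top-view camera method would report; it can only underestimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_model import LabeledPointCloud, ShredInstance
from .registration import GaugeReference

log = logging.getLogger(__name__)


@dataclass
class ProjectionImage:
    """Grayscale projection of a surface cloud on the scan grid."""

    pixels: np.ndarray  # uint8, (rows, cols)
    pixel_to_mm: float
    height_window: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)  # mm of pixel (0, 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8 (gray 0..255)")


@dataclass
class SkeletonPolyline:
    """Ordered centerline points of one filament, with optional
    per-segment width samples (midpoint, left and right contour
    intersections, all 3-D)."""

    centers: np.ndarray
    width_samples: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 3)
        if self.centers.shape[1] != 3:
            raise ValueError("centers must have shape (n, 3)")

    @property
    def measurable(self) -> bool:
        return len(self.centers) >= 2


@dataclass
class Measurement:
    """Per-shred result; lengths in mm.  NaN marks a quantity a flagged
    failure prevented from being computed."""

    instance_id: int
    class_label: int
    length_mm: float
    width_avg_mm: float
    width_max_mm: float
    thickness_mm: float
    projected_length_mm: float = float("nan")
    n_points: int = 0
    flags: tuple[str, ...] = ()


@dataclass
class MeasureConfig:
    """Knobs of the measurement stage.

    pixel_to_mm is the scan-grid pitch; band_height (pixels) sets the
    skeleton segmentation granularity; lift_cutoff (mm, default
    5 pitches) flags skeleton points with no nearby cloud support.
    """

    pixel_to_mm: float = 0.05
    band_height: int = 5
    min_instance_points: int = 30
    lift_neighbors: int = 4
    lift_cutoff: float | None = None
    width_step_px: float = 0.25
    height_window: tuple[float, float] = (26000.0, 28000.0)

    def cutoff(self) -> float:
        return self.lift_cutoff if self.lift_cutoff is not None else 5.0 * self.pixel_to_mm


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def project_to_image(
    cloud: LabeledPointCloud | np.ndarray,
    height_window: tuple[float, float],
    pixel_to_mm: float,
) -> ProjectionImage:
    """Map a surface cloud to a grayscale image.

    Heights inside ``height_window`` map linearly to gray 0..255
    (rounded half-up); out-of-window points leave their pixel at
    background 0.  x, y bin to the nearest pixel; overlapping points
    keep the brightest gray.
    """
    pts = cloud.points if isinstance(cloud, LabeledPointCloud) else np.asarray(cloud)
    if len(pts) == 0:
        raise ValueError("empty cloud")
    lo, hi = height_window
    if not lo < hi:
        raise ValueError("height window must satisfy lo < hi")
    origin = (float(pts[:, 0].min()), float(pts[:, 1].min()))
    cols = np.rint((pts[:, 0] - origin[0]) / pixel_to_mm).astype(np.int64)
    rows = np.rint((pts[:, 1] - origin[1]) / pixel_to_mm).astype(np.int64)
    img = np.zeros((rows.max() + 1, cols.max() + 1), dtype=np.uint8)
    z = pts[:, 2]
    inside = (z >= lo) & (z <= hi)
    gray = _round_half_up(255.0 * (z[inside] - lo) / (hi - lo)).astype(np.uint8)
    np.maximum.at(img, (rows[inside], cols[inside]), gray)
    return ProjectionImage(img, pixel_to_mm, (lo, hi), origin)


def points_to_mask(
    points: np.ndarray,
    pixel_to_mm: float,
    origin: tuple[float, float],
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean occupancy mask of points binned onto a pixel grid."""
    cols = np.rint((points[:, 0] - origin[0]) / pixel_to_mm).astype(np.int64)
    rows = np.rint((points[:, 1] - origin[1]) / pixel_to_mm).astype(np.int64)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    mask = np.zeros(shape, dtype=bool)
    mask[rows[ok], cols[ok]] = True
    return mask


def _chain_centers(centers: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour chaining, starting from the center with
    minimal y (then minimal x); every center used exactly once."""
    n = len(centers)
    start = int(np.lexsort((centers[:, 0], centers[:, 1]))[0])
    remaining = set(range(n)) - {start}
    order = [start]
    while remaining:
        cur = centers[order[-1]]
        rem = np.fromiter(remaining, dtype=np.int64)
        d2 = np.sum((centers[rem, :2] - cur[:2]) ** 2, axis=1)
        nxt = int(rem[np.argmin(d2)])
        order.append(nxt)
        remaining.discard(nxt)
    return centers[order]


def extract_skeleton(
    instance_mask: np.ndarray,
    band_height: int,
    pixel_to_mm: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    min_run_pixels: int = 3,
) -> SkeletonPolyline:
    """Band-wise skeleton of a 2-D instance mask.

    The mask is cut into horizontal bands of ``band_height`` rows; each
    connected run of mask columns within a band contributes one center
    (the centroid of its pixels), so two filaments crossing a band give
    two centers.  Runs smaller than ``min_run_pixels`` are
    sub-resolution fragments (typically corners of a filament's oblique
    cut end) and are ignored.  Centers are chained by greedy nearest
    neighbour from the lowest-y center.  Coordinates are returned in mm
    with z = 0 (lift separately).
    """
    mask = np.asarray(instance_mask, dtype=bool)
    if band_height < 1:
        raise ValueError("band_height must be >= 1")
    if not mask.any():
        raise ValueError("empty instance mask")
    centers = []
    n_rows = mask.shape[0]
    for r0 in range(0, n_rows, band_height):
        band = mask[r0 : r0 + band_height]
        occupied = band.any(axis=0)
        if not occupied.any():
            continue
        # connected runs of occupied columns
        edges = np.diff(np.concatenate([[0], occupied.astype(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for c0, c1 in zip(starts, ends):
            rr, cc = np.nonzero(band[:, c0:c1])
            if len(rr) < min_run_pixels:
                continue
            centers.append(
                (
                    origin[0] + (cc.mean() + c0) * pixel_to_mm,
                    origin[1] + (rr.mean() + r0) * pixel_to_mm,
                    0.0,
                )
            )
    centers = np.asarray(centers, dtype=np.float64).reshape(-1, 3)
    if len(centers) >= 2:
        centers = _chain_centers(centers)
        keep = np.ones(len(centers), dtype=bool)  # drop coincident consecutive centers
        keep[1:] = np.linalg.norm(np.diff(centers, axis=0), axis=1) > 1e-12
        centers = centers[keep]
    if len(centers) < 2:
        log.warning("degenerate skeleton: %d center(s)", len(centers))
    return SkeletonPolyline(centers)


def _prune_end_spurs(
    centers: np.ndarray, lateral_ratio: float = 1.5, max_iter: int = 3
) -> np.ndarray:
    """Drop terminal centers whose segment steps mostly sideways.

    Bands advance along y, so consecutive genuine centers always make
    headway in y (tangents stay well under the banding axis' normal).
    A filament's oblique cut end, however, leaves a wedge in the
    terminal band whose centroid sits beside the centerline, producing
    a terminal segment that moves laterally (|Δx| ≫ |Δy|).  Such end
    spurs are pruned, at most ``max_iter`` per end."""
    for _ in range(max_iter):
        if len(centers) < 3:
            break
        changed = False
        for end in (0, -1):
            if len(centers) < 3:
                break
            if end == 0:
                d = centers[1, :2] - centers[0, :2]
            else:
                d = centers[-1, :2] - centers[-2, :2]
            if abs(d[0]) > lateral_ratio * abs(d[1]):
                centers = centers[1:] if end == 0 else centers[:-1]
                changed = True
        if not changed:
            break
    return centers


def lift_to_3d(
    xy: np.ndarray,
    cloud: LabeledPointCloud | np.ndarray,
    m: int = 4,
    cutoff: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lift 2-D query points onto the surface cloud.

    z at each query is the inverse-distance-weighted mean of the ``m``
    nearest cloud points in x,y (an exact x,y hit returns that point's
    z).  Queries whose nearest neighbour exceeds ``cutoff`` are flagged
    unmapped.  Returns ``(points_3d, mapped_mask)``.
    """
    pts = cloud.points if isinstance(cloud, LabeledPointCloud) else np.asarray(cloud)
    if len(pts) == 0:
        raise ValueError("empty cloud")
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))[:, :2]
    k = min(m, len(pts))
    tree = cKDTree(pts[:, :2])
    d, idx = tree.query(xy, k=k)
    d = d.reshape(len(xy), k)
    idx = idx.reshape(len(xy), k)
    w = 1.0 / np.maximum(d, 1e-12)
    exact = d[:, 0] < 1e-12
    z = np.einsum("nk,nk->n", w, pts[idx, 2]) / w.sum(axis=1)
    z[exact] = pts[idx[exact, 0], 2]
    mapped = np.ones(len(xy), dtype=bool)
    if cutoff is not None:
        mapped = d[:, 0] <= cutoff
    return np.column_stack([xy, z]), mapped


def measure_length(skeleton: SkeletonPolyline) -> float:
    """3-D polyline arc length: sum of consecutive center distances."""
    if not skeleton.measurable:
        raise ValueError("skeleton needs >= 2 centers")
    return float(np.linalg.norm(np.diff(skeleton.centers, axis=0), axis=1).sum())


def projected_length_2d(skeleton: SkeletonPolyline) -> float:
    """Length with the z term dropped — the top-view camera baseline."""
    if not skeleton.measurable:
        raise ValueError("skeleton needs >= 2 centers")
    return float(np.linalg.norm(np.diff(skeleton.centers[:, :2], axis=0), axis=1).sum())


def _mask_lookup(mask: np.ndarray, pixel_to_mm: float, origin: tuple[float, float],
                 pts_xy: np.ndarray) -> np.ndarray:
    rows = np.rint((pts_xy[:, 1] - origin[1]) / pixel_to_mm).astype(np.int64)
    cols = np.rint((pts_xy[:, 0] - origin[0]) / pixel_to_mm).astype(np.int64)
    ok = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    out = np.zeros(len(pts_xy), dtype=bool)
    out[ok] = mask[rows[ok], cols[ok]]
    return out


def measure_width(
    skeleton: SkeletonPolyline,
    instance_mask: np.ndarray,
    cloud: LabeledPointCloud | np.ndarray,
    pixel_to_mm: float,
    origin: tuple[float, float] = (0.0, 0.0),
    step_px: float = 0.25,
    lift_neighbors: int = 4,
) -> tuple[float, float]:
    """Average and maximum 3-D width over the skeleton segments.

    For each consecutive center pair, a perpendicular is cast through
    the segment midpoint in the image plane and marched (sub-pixel
    steps) until it leaves the instance mask on each side; the midpoint
    and the two contour intersections are lifted to 3-D and the width
    is the sum of the two midpoint-to-intersection distances.  Segments
    whose perpendicular fails to produce both intersections are skipped
    and logged.  Width samples are stored on the skeleton.
    """
    if not skeleton.measurable:
        raise ValueError("skeleton needs >= 2 centers")
    step = step_px * pixel_to_mm
    max_range = (math.hypot(*instance_mask.shape) + 2) * pixel_to_mm
    ts = np.arange(step, max_range, step)
    widths = []
    skeleton.width_samples = []
    n_seg = len(skeleton.centers) - 1
    pairs = list(zip(skeleton.centers[:-1], skeleton.centers[1:]))
    if n_seg > 4:
        # end bands are contaminated by the filament's cut end faces, which
        # skew the terminal centers and tilt their perpendiculars
        pairs = pairs[1:-1]
    for a, b in pairs:
        mid = (a[:2] + b[:2]) / 2.0
        d = b[:2] - a[:2]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        perp = np.array([-d[1], d[0]]) / norm
        ends = []
        for sgn in (+1.0, -1.0):
            samples = mid[None, :] + sgn * ts[:, None] * perp[None, :]
            inside = _mask_lookup(instance_mask, pixel_to_mm, origin, samples)
            if inside[0] and not inside.all():
                first_out = int(np.argmin(inside))
                # sub-pixel contour estimate: the march flips at the last
                # occupied pixel's boundary, which overshoots the true edge
                # by half a pixel on average — correct for both
                t_edge = ts[first_out] - step / 2.0 - pixel_to_mm / 2.0
                if t_edge > 0:
                    ends.append(mid + sgn * t_edge * perp)
        if len(ends) != 2:
            log.debug("width profile without 2 intersections; segment skipped")
            continue
        lifted, mapped = lift_to_3d(
            np.vstack([mid, ends[0], ends[1]]), cloud, m=lift_neighbors
        )
        if not mapped.all():
            continue
        w = float(
            np.linalg.norm(lifted[1] - lifted[0]) + np.linalg.norm(lifted[2] - lifted[0])
        )
        widths.append(w)
        skeleton.width_samples.append((lifted[0], lifted[1], lifted[2]))
    if not widths:
        log.warning("no valid width profiles for instance")
        return float("nan"), float("nan")
    widths = np.asarray(widths)
    # a profile several times wider than the median ran along the trunk
    # (a skeleton artifact), not across it; drop it rather than average it
    keep = widths <= 2.5 * np.median(widths)
    if not keep.all():
        log.info("dropped %d along-trunk width profiles", int((~keep).sum()))
        widths = widths[keep]
        skeleton.width_samples = [
            s for s, k in zip(skeleton.width_samples, keep) if k
        ]
    wm_val = float(np.max(widths))
    wa_val = min(float(np.mean(widths)), wm_val)  # guard fp summation wobble
    return wa_val, wm_val


def measure_thickness(
    instance: ShredInstance, gauge: GaugeReference
) -> tuple[float, str]:
    """Gauge-referenced thickness of one shred from registered clouds.

    H1 = |mean upper-surface z of shred − mean upper-surface z of the
    gauge|, H2 likewise for the lower surfaces; the gauge surface
    heights are taken from its reference points.  The case split
    follows whether the shred's upper surface lies below or above the
    gauge top.  Returns ``(T, case)``; a non-positive T indicates an
    inconsistent registration and is returned unclamped for the caller
    to flag.
    """
    if len(instance.lower_points) == 0:
        raise ValueError("instance has no lower-surface points")
    gauge_up = float(gauge.upper_points[:, 2].mean())
    gauge_lo = float(gauge.lower_points[:, 2].mean())
    shred_up = float(instance.upper_points[:, 2].mean())
    shred_lo = float(instance.lower_points[:, 2].mean())
    h1 = abs(shred_up - gauge_up)
    h2 = abs(shred_lo - gauge_lo)
    if shred_up <= gauge_up:
        return gauge.thickness - h1 - h2, "below"
    return gauge.thickness + h1 - h2, "above"


# ---------------------------------------------------------------------------
# scene orchestration


def _principal_angle(xy: np.ndarray) -> float:
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    _, evecs = np.linalg.eigh(cov)
    u = evecs[:, 1]
    return math.atan2(u[1], u[0])


def _rotate_z(points: np.ndarray, theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    out = points.copy()
    out[:, 0] = c * points[:, 0] - s * points[:, 1]
    out[:, 1] = s * points[:, 0] + c * points[:, 1]
    return out


def measure_instance_dimensions(
    upper_points: np.ndarray, config: MeasureConfig
) -> tuple[float, float, float, float, SkeletonPolyline, list[str]]:
    """Length / width measurement of one instance's upper-surface points.

    The instance is rotated in-plane so its principal axis is vertical
    (the skeleton bands cut across the main trunk), rasterised at the
    grid pitch, skeletonised, lifted, and measured.  Returns
    ``(length, width_avg, width_max, projected_length, skeleton, flags)``
    with NaNs where a step failed.
    """
    flags: list[str] = []
    pts = np.asarray(upper_points, dtype=np.float64)
    theta = _principal_angle(pts[:, :2])
    rot = _rotate_z(pts, math.pi / 2.0 - theta)
    p = config.pixel_to_mm
    origin = (float(rot[:, 0].min()), float(rot[:, 1].min()))
    shape = (
        int(np.rint((rot[:, 1].max() - origin[1]) / p)) + 1,
        int(np.rint((rot[:, 0].max() - origin[0]) / p)) + 1,
    )
    mask = points_to_mask(rot, p, origin, shape)
    # close single-pixel aliasing holes left by re-binning rotated grid
    # samples; pad first so the closing cannot erode the true boundary
    padded = np.pad(mask, 2)
    padded = ndimage.binary_closing(padded, structure=np.ones((3, 3), dtype=bool))
    mask = padded[2:-2, 2:-2]
    skeleton = extract_skeleton(mask, config.band_height, p, origin)
    skeleton.centers = _prune_end_spurs(skeleton.centers)
    if not skeleton.measurable:
        return (float("nan"),) * 4 + (skeleton, ["degenerate_skeleton"])  # type: ignore[return-value]
    lifted, mapped = lift_to_3d(
        skeleton.centers[:, :2], rot, m=config.lift_neighbors, cutoff=config.cutoff()
    )
    if not mapped.all():
        flags.append("unmapped_skeleton_points")
        lifted = lifted[mapped]
    if len(lifted) < 2:
        return (float("nan"),) * 4 + (skeleton, flags + ["degenerate_skeleton"])  # type: ignore[return-value]
    skeleton.centers = lifted
    length = measure_length(skeleton)
    proj = projected_length_2d(skeleton)
    wa, wm = measure_width(
        skeleton, mask, rot, p, origin,
        step_px=config.width_step_px, lift_neighbors=config.lift_neighbors,
    )
    if math.isnan(wa):
        flags.append("no_width_profiles")
    return length, wa, wm, proj, skeleton, flags


def _scene_instances(
    upper: LabeledPointCloud, lower: LabeledPointCloud, config: MeasureConfig
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Split shred-class points into instances by 8-connected components
    of same-label pixels; returns (class_label, upper_idx, lower_idx)."""
    p = config.pixel_to_mm
    all_xy = np.vstack([upper.points[:, :2], lower.points[:, :2]])
    origin = (float(all_xy[:, 0].min()) - p, float(all_xy[:, 1].min()) - p)
    shape = (
        int(np.rint((all_xy[:, 1].max() - origin[1]) / p)) + 2,
        int(np.rint((all_xy[:, 0].max() - origin[0]) / p)) + 2,
    )
    eight = np.ones((3, 3), dtype=int)
    out = []
    for c in range(4):
        up_idx = np.flatnonzero(upper.labels == c)
        if len(up_idx) == 0:
            continue
        mask = points_to_mask(upper.points[up_idx], p, origin, shape)
        comp, n_comp = ndimage.label(mask, structure=eight)
        rows = np.rint((upper.points[up_idx, 1] - origin[1]) / p).astype(np.int64)
        cols = np.rint((upper.points[up_idx, 0] - origin[0]) / p).astype(np.int64)
        comp_of_point = comp[rows, cols]
        lo_idx = np.flatnonzero(lower.labels == c)
        if len(lo_idx):
            lrows = np.rint((lower.points[lo_idx, 1] - origin[1]) / p).astype(np.int64)
            lcols = np.rint((lower.points[lo_idx, 0] - origin[0]) / p).astype(np.int64)
            lrows = np.clip(lrows, 0, shape[0] - 1)
            lcols = np.clip(lcols, 0, shape[1] - 1)
        for comp_id in range(1, n_comp + 1):
            ui = up_idx[comp_of_point == comp_id]
            if len(ui) < config.min_instance_points:
                continue
            if len(lo_idx):
                comp_mask = ndimage.binary_dilation(comp == comp_id, structure=eight,
                                                    iterations=2)
                li = lo_idx[comp_mask[lrows, lcols]]
            else:
                li = np.empty(0, dtype=np.int64)
            out.append((c, ui, li))
    return out


def measure_scene(
    upper: LabeledPointCloud,
    lower: LabeledPointCloud,
    gauge: GaugeReference | None,
    config: MeasureConfig | None = None,
    labels: np.ndarray | None = None,
) -> list[Measurement]:
    """Measure every shred instance of a segmented, registered scene.

    Instances are connected components of same-label pixels (classes
    0–3; background and the gauge never produce measurements).  Stage
    failures become per-instance flags, never exceptions.  Thickness
    requires a gauge reference and matched lower-surface points;
    otherwise it is NaN with a flag.
    """
    config = config or MeasureConfig()
    if labels is not None:
        upper = LabeledPointCloud(upper.points, labels, upper.surface)
    results: list[Measurement] = []
    for inst_id, (c, ui, li) in enumerate(_scene_instances(upper, lower, config)):
        up_pts = upper.points[ui]
        length, wa, wm, proj, _, flags = measure_instance_dimensions(up_pts, config)
        thickness = float("nan")
        if gauge is None:
            flags = list(flags) + ["no_gauge_reference"]
        elif len(li) == 0:
            flags = list(flags) + ["no_lower_surface_points"]
        else:
            inst = ShredInstance(c, up_pts, lower.points[li])
            thickness, _case = measure_thickness(inst, gauge)
            if thickness <= 0:
                flags = list(flags) + ["invalid_thickness"]
        results.append(
            Measurement(
                instance_id=inst_id,
                class_label=c,
                length_mm=length,
                width_avg_mm=wa,
                width_max_mm=wm,
                thickness_mm=thickness,
                projected_length_mm=proj,
                n_points=len(ui),
                flags=tuple(flags),
            )
        )
    return results


def measurements_to_frame(measurements: list[Measurement]):
    """Tabulate measurements (one row per instance) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "instance_id": m.instance_id,
                "class": m.class_label,
                "length_mm": m.length_mm,
                "width_avg_mm": m.width_avg_mm,
                "width_max_mm": m.width_max_mm,
                "thickness_mm": m.thickness_mm,
                "projected_length_mm": m.projected_length_mm,
                "n_points": m.n_points,
                "flags": ";".join(m.flags),
            }
            for m in measurements
        ]
    )
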