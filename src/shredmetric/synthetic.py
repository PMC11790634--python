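"""Synthetic dual-surface scan generator with exact ground truth.

Emulates the line-scanner acquisition geometry at desk scale: objects
(a precision gauge block, rectangular slabs, and curved ribbon-like
filaments) rest on a transparent stage and are sampled on a regular
x,y grid from above and from below, giving an upper and a lower
height field.  Ground-truth dimensions (arc length, width, thickness)
are known in closed form or by high-resolution quadrature, so every
downstream stage can be tested by parameter recovery.

Conventions
-----------
* Heights are in mm; the sensor-count scale is ``COUNT_TO_MM`` mm per
  count (so the canonical surface band [26, 28] mm corresponds to
  counts [26000, 28000]; the stage top sits at 26.5 mm and the scene
  background at 20 mm, outside the band, so ROI cropping by z works).
* Sensor noise is independent Gaussian: σ_z = 0.0005 mm on heights and
  σ_x = 0.0025 mm along the profile axis (the scanner's static
  precisions).
* The lower scanner's z origin is arbitrary on a real rig; the scene
  generator emits the lower cloud in a frame calibrated so the gauge
  reference surfaces coincide when no misalignment is injected, then
  subtracts the configured misalignment offset — registration must
  recover exactly that offset.  The standalone gauge-block generator
  emits geometric surfaces (upper − lower = thickness).

Filament cross-sections are rectangular (width × thickness), optionally
tilted about the long axis; centerlines are circular arcs or planar
sinusoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import BACKGROUND_LABEL, HeightMap, LabeledPointCloud

COUNT_TO_MM = 1e-3  # mm per sensor count
STAGE_Z = 26.5  # mm, top of the transparent stage
BACKGROUND_Z = 20.0  # mm, background plane (outside the surface band)
HEIGHT_WINDOW_MM = (26.0, 28.0)
HEIGHT_WINDOW_COUNTS = (26000.0, 28000.0)
DEFAULT_PITCH = 0.05  # mm per grid step
DEFAULT_SIGMA_Z = 0.0005  # mm
DEFAULT_SIGMA_X = 0.0025  # mm


@dataclass
class GaugeBlockSpec:
    """Rectangular slab: the reference gauge (30 x 9 x 0.5 mm nominal)
    or a measurable block when ``label`` is a shred class."""

    length: float = 30.0
    width: float = 9.0
    thickness: float = 0.5
    center: tuple[float, float] = (15.0, 5.0)
    angle_deg: float = 0.0  # rotation of the length axis from +x
    label: int = BACKGROUND_LABEL

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.thickness) <= 0:
            raise ValueError("block dimensions must be > 0")

    def footprint_bbox(self) -> tuple[float, float, float, float]:
        a = math.radians(self.angle_deg)
        hx = abs(math.cos(a)) * self.length / 2 + abs(math.sin(a)) * self.width / 2
        hy = abs(math.sin(a)) * self.length / 2 + abs(math.cos(a)) * self.width / 2
        cx, cy = self.center
        return cx - hx, cx + hx, cy - hy, cy + hy


@dataclass
class FilamentSpec:
    """Curved ribbon filament with known dimensions.

    ``kind`` is ``"arc"`` (circular arc of the given radius) or
    ``"sine"`` (planar sinusoid with amplitude/wavelength); the swept
    ribbon has the given width and thickness and may be tilted about
    its long axis.  ``start`` and ``heading_deg`` place the centerline
    in the scene.
    """

    arc_length: float = 20.0
    width: float = 1.0
    thickness: float = 0.1
    kind: str = "arc"
    radius: float = 25.0
    amplitude: float = 2.0
    wavelength: float = 15.0
    tilt_deg: float = 0.0
    class_label: int = 1
    start: tuple[float, float] = (2.0, 2.0)
    heading_deg: float = 90.0

    def __post_init__(self) -> None:
        if min(self.arc_length, self.width, self.thickness) <= 0:
            raise ValueError("filament dimensions must be > 0")
        if self.class_label not in range(4):
            raise ValueError("class_label must be in 0..3")
        if self.kind not in ("arc", "sine"):
            raise ValueError("kind must be 'arc' or 'sine'")
        if self.kind == "arc" and self.arc_length >= 1.9 * math.pi * self.radius:
            raise ValueError("arc sweeps nearly the full circle (self-intersecting ribbon)")


@dataclass
class SceneSpec:
    """Full dual-surface scene: gauge + slabs + filaments + background."""

    filaments: list[FilamentSpec] = field(default_factory=list)
    gauge: GaugeBlockSpec | None = field(default_factory=GaugeBlockSpec)
    slabs: list[GaugeBlockSpec] = field(default_factory=list)
    pitch: float = DEFAULT_PITCH
    sigma_z: float = DEFAULT_SIGMA_Z
    sigma_x: float = DEFAULT_SIGMA_X
    lower_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rng_seed: int = 0
    stage_z: float = STAGE_Z
    background_z: float = BACKGROUND_Z
    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")


@dataclass
class SceneTruth:
    """Exact generator ground truth for one scene."""

    objects: pd.DataFrame
    lower_offset: np.ndarray
    upper_object_ids: np.ndarray  # per upper point; -1 = background
    lower_object_ids: np.ndarray


# ---------------------------------------------------------------------------
# centerlines


def _centerline(spec: FilamentSpec, ds: float) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length-parametrised centerline samples and unit tangents in
    the scene plane, spaced ``ds`` along the curve."""
    n = max(int(math.ceil(spec.arc_length / ds)) + 1, 8)
    s = np.linspace(0.0, spec.arc_length, n)
    if spec.kind == "arc":
        r = spec.radius
        ang = s / r
        pts = np.column_stack([r * np.sin(ang), r * (1.0 - np.cos(ang))])
        tans = np.column_stack([np.cos(ang), np.sin(ang)])
    else:
        # sinusoid x(t) = t, y = A sin(2 pi t / lambda); solve t range for
        # the requested arc length on a dense table, then resample evenly.
        k = 2.0 * math.pi / spec.wavelength
        t_hi = spec.arc_length  # arc length >= t span, so this bounds t
        t_dense = np.linspace(0.0, t_hi, 20000)
        speed = np.sqrt(1.0 + (spec.amplitude * k * np.cos(k * t_dense)) ** 2)
        arc = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0
                                               * np.diff(t_dense))])
        t_of_s = np.interp(s, arc, t_dense)
        pts = np.column_stack([t_of_s, spec.amplitude * np.sin(k * t_of_s)])
        d = np.column_stack([np.ones_like(t_of_s), spec.amplitude * k * np.cos(k * t_of_s)])
        tans = d / np.linalg.norm(d, axis=1, keepdims=True)
    # place: rotate by heading, translate to start
    h = math.radians(spec.heading_deg)
    rot = np.array([[math.cos(h), -math.sin(h)], [math.sin(h), math.cos(h)]])
    pts = pts @ rot.T + np.asarray(spec.start)
    tans = tans @ rot.T
    return pts, tans


def _check_self_intersection(pts: np.ndarray, width: float) -> None:
    """Error if non-adjacent centerline portions come closer than the
    ribbon width (the swept solid would overlap itself)."""
    stride = max(len(pts) // 400, 1)
    sub = pts[::stride]
    n = len(sub)
    seg = np.linalg.norm(np.diff(sub, axis=0), axis=1)
    ds = seg.mean() if len(seg) else 1.0
    # points separated by more than ~2 widths along the curve must stay
    # at least one width apart in the plane
    min_gap = max(int(math.ceil(2.0 * width / max(ds, 1e-9))), 2)
    d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    if (d[np.abs(i - j) > min_gap] < width).any():
        raise ValueError("self-intersecting centerline for the given width")


# ---------------------------------------------------------------------------
# surface sampling and rasterisation


def _rasterize(
    samples: np.ndarray, pitch: float, mode: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scanner emulation: bin dense surface samples to the grid, keeping
    the topmost (``mode='upper'``) or bottommost (``'lower'``) height
    per pixel.  Returns (col, row, z) arrays of occupied pixels."""
    cols = np.rint(samples[:, 0] / pitch).astype(np.int64)
    rows = np.rint(samples[:, 1] / pitch).astype(np.int64)
    c0, r0 = cols.min(), rows.min()
    shape = (rows.max() - r0 + 1, cols.max() - c0 + 1)
    init = -np.inf if mode == "upper" else np.inf
    buf = np.full(shape, init)
    if mode == "upper":
        np.maximum.at(buf, (rows - r0, cols - c0), samples[:, 2])
    else:
        np.minimum.at(buf, (rows - r0, cols - c0), samples[:, 2])
    rr, cc = np.nonzero(np.isfinite(buf))
    return cc + c0, rr + r0, buf[rr, cc]


def _filament_surface_samples(spec: FilamentSpec, pitch: float, stage_z: float) -> np.ndarray:
    """Dense samples of the swept ribbon's four long faces (3-D)."""
    fine = pitch / 3.0
    pts2, tans = _centerline(spec, fine)
    _check_self_intersection(pts2, spec.width)
    tau = math.radians(spec.tilt_deg)
    normals = np.column_stack([-tans[:, 1], tans[:, 0]])
    # cross-section frame: u = cos(tau) n + sin(tau) z ; v = -sin(tau) n + cos(tau) z
    cu, su = math.cos(tau), math.sin(tau)
    half_w, half_t = spec.width / 2.0, spec.thickness / 2.0
    z_c = stage_z + half_w * abs(su) + half_t * cu  # rest the solid on the stage
    a_vals = np.arange(-half_w, half_w + fine / 2, fine)
    b_vals = np.arange(-half_t, half_t + fine / 2, fine)
    faces = []
    for a, b in [(a_vals, np.array([half_t])), (a_vals, np.array([-half_t])),
                 (np.array([half_w]), b_vals), (np.array([-half_w]), b_vals)]:
        A, B = np.meshgrid(a, b, indexing="ij")
        A, B = A.ravel(), B.ravel()
        # broadcast over centerline samples: (n_center, n_face, ...)
        off_n = A * cu - B * su  # in-plane offset along the local normal
        off_z = A * su + B * cu  # vertical offset (same for every centerline sample)
        xy = pts2[:, None, :] + off_n[None, :, None] * normals[:, None, :]
        z = np.broadcast_to(z_c + off_z[None, :], xy.shape[:2])
        faces.append(
            np.column_stack([xy.reshape(-1, 2), z.reshape(-1, 1)])
        )
    return np.vstack(faces)


def generate_filament(
    spec: FilamentSpec,
    scene: SceneSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sample one filament on the scan grid from both sides.

    Returns ``(upper_points, lower_points, truth)`` where the point
    arrays are (n, 3) in mm (grid-snapped x,y with sensor noise
    applied) and ``truth`` records the exact arc length, width,
    thickness and tilt.
    """
    if rng is None:
        rng = np.random.default_rng(scene.rng_seed)
    samples = _filament_surface_samples(spec, scene.pitch, scene.stage_z)
    out = []
    for mode in ("upper", "lower"):
        cols, rows, z = _rasterize(samples, scene.pitch, mode)
        pts = np.column_stack([cols * scene.pitch, rows * scene.pitch, z])
        if scene.sigma_x > 0:
            pts[:, 0] += rng.normal(0.0, scene.sigma_x, len(pts))
        if scene.sigma_z > 0:
            pts[:, 2] += rng.normal(0.0, scene.sigma_z, len(pts))
        out.append(pts)
    truth = {
        "kind": spec.kind,
        "class_label": spec.class_label,
        "arc_length": spec.arc_length,
        "width": spec.width,
        "thickness": spec.thickness,
        "tilt_deg": spec.tilt_deg,
    }
    return out[0], out[1], truth


def _block_pixels(
    spec: GaugeBlockSpec, pitch: float
) -> tuple[np.ndarray, np.ndarray]:
    """(col, row) grid indices covered by the block footprint."""
    x0, x1, y0, y1 = spec.footprint_bbox()
    cols = np.arange(int(math.floor(x0 / pitch)), int(math.ceil(x1 / pitch)) + 1)
    rows = np.arange(int(math.floor(y0 / pitch)), int(math.ceil(y1 / pitch)) + 1)
    C, R = np.meshgrid(cols, rows, indexing="xy")
    x = C * pitch - spec.center[0]
    y = R * pitch - spec.center[1]
    a = math.radians(spec.angle_deg)
    u = x * math.cos(a) + y * math.sin(a)
    v = -x * math.sin(a) + y * math.cos(a)
    inside = (np.abs(u) <= spec.length / 2) & (np.abs(v) <= spec.width / 2)
    return C[inside], R[inside]


def generate_gauge_block(
    spec: GaugeBlockSpec | None = None,
    pitch: float = DEFAULT_PITCH,
    stage_z: float = STAGE_Z,
    background_z: float = BACKGROUND_Z,
    margin: float = 1.0,
    sigma_z: float = 0.0,
    count_to_mm: float = COUNT_TO_MM,
    rng_seed: int = 0,
) -> tuple[HeightMap, HeightMap, dict]:
    """Dual-surface height maps of a rectangular slab on the stage.

    Geometric surfaces: the upper map holds the top face (stage +
    thickness), the lower map the bottom face (stage level); their
    difference over the footprint is the thickness everywhere.  Pixels
    outside the footprint hold the background plane.  Heights are in
    sensor counts (``count_to_mm`` mm per count).  Deterministic for a
    fixed ``rng_seed``.
    """
    spec = spec or GaugeBlockSpec()
    rng = np.random.default_rng(rng_seed)
    cols, rows = _block_pixels(spec, pitch)
    x0, x1, y0, y1 = spec.footprint_bbox()
    mc = int(math.ceil(margin / pitch))
    c_lo, r_lo = cols.min() - mc, rows.min() - mc
    shape = (rows.max() - r_lo + 1 + mc, cols.max() - c_lo + 1 + mc)
    up = np.full(shape, background_z / count_to_mm)
    lo = np.full(shape, background_z / count_to_mm)
    up[rows - r_lo, cols - c_lo] = (stage_z + spec.thickness) / count_to_mm
    lo[rows - r_lo, cols - c_lo] = stage_z / count_to_mm
    if sigma_z > 0:
        up += rng.normal(0.0, sigma_z / count_to_mm, shape)
        lo += rng.normal(0.0, sigma_z / count_to_mm, shape)
    truth = {
        "kind": "block",
        "class_label": spec.label,
        "length": spec.length,
        "width": spec.width,
        "thickness": spec.thickness,
        "center": spec.center,
        "angle_deg": spec.angle_deg,
        "grid_origin": (c_lo, r_lo),
    }
    return (
        HeightMap(up, pitch, pitch),
        HeightMap(lo, pitch, pitch),
        truth,
    )


def generate_scene(
    spec: SceneSpec,
) -> tuple[LabeledPointCloud, LabeledPointCloud, SceneTruth]:
    """Compose gauge + slabs + filaments over a flat background into a
    dual-surface labeled scene with exact ground truth.

    Objects may not overlap in x,y footprint (error naming the pair).
    Sensor noise and the lower-surface misalignment are applied here;
    the truth table records every object's exact dimensions and the
    injected offset.
    """
    rng = np.random.default_rng(spec.rng_seed)
    blocks: list[tuple[str, GaugeBlockSpec]] = []
    if spec.gauge is not None:
        blocks.append(("gauge", spec.gauge))
    blocks.extend(("slab", s) for s in spec.slabs)

    bboxes: list[tuple[str, tuple[float, float, float, float]]] = []
    for name, b in blocks:
        bboxes.append((name, b.footprint_bbox()))
    fil_geom = []
    for i, f in enumerate(spec.filaments):
        pts2, _ = _centerline(f, spec.pitch / 2)
        half = (f.width + f.thickness) / 2 + spec.pitch
        bboxes.append(
            (f"filament{i}", (pts2[:, 0].min() - half, pts2[:, 0].max() + half,
                              pts2[:, 1].min() - half, pts2[:, 1].max() + half))
        )
        fil_geom.append(pts2)
    for i in range(len(bboxes)):
        for j in range(i + 1, len(bboxes)):
            (na, a), (nb, bb) = bboxes[i], bboxes[j]
            if a[0] < bb[1] and bb[0] < a[1] and a[2] < bb[3] and bb[2] < a[3]:
                raise ValueError(f"objects overlap in x,y footprint: {na} and {nb}")

    # scene grid
    x_lo = min(b[0] for _, b in bboxes) - spec.margin
    x_hi = max(b[1] for _, b in bboxes) + spec.margin
    y_lo = min(b[2] for _, b in bboxes) - spec.margin
    y_hi = max(b[3] for _, b in bboxes) + spec.margin
    c_lo, c_hi = int(math.floor(x_lo / spec.pitch)), int(math.ceil(x_hi / spec.pitch))
    r_lo, r_hi = int(math.floor(y_lo / spec.pitch)), int(math.ceil(y_hi / spec.pitch))
    shape = (r_hi - r_lo + 1, c_hi - c_lo + 1)
    z_up = np.full(shape, spec.background_z)
    z_lo_buf = np.full(shape, spec.background_z)
    labels = np.full(shape, BACKGROUND_LABEL, dtype=np.int64)
    obj_ids = np.full(shape, -1, dtype=np.int64)

    records = []
    obj_id = 0
    for name, b in blocks:
        cols, rows = _block_pixels(b, spec.pitch)
        z_up[rows - r_lo, cols - c_lo] = spec.stage_z + b.thickness
        z_lo_buf[rows - r_lo, cols - c_lo] = spec.stage_z
        labels[rows - r_lo, cols - c_lo] = b.label
        obj_ids[rows - r_lo, cols - c_lo] = obj_id
        records.append(
            {"object_id": obj_id, "kind": name, "class_label": b.label,
             "length": b.length, "width": b.width, "thickness": b.thickness}
        )
        obj_id += 1
    for f in spec.filaments:
        samples = _filament_surface_samples(f, spec.pitch, spec.stage_z)
        for mode, buf in (("upper", z_up), ("lower", z_lo_buf)):
            cols, rows, z = _rasterize(samples, spec.pitch, mode)
            buf[rows - r_lo, cols - c_lo] = z
            if mode == "upper":
                labels[rows - r_lo, cols - c_lo] = f.class_label
                obj_ids[rows - r_lo, cols - c_lo] = obj_id
        records.append(
            {"object_id": obj_id, "kind": f.kind, "class_label": f.class_label,
             "length": f.arc_length, "width": f.width, "thickness": f.thickness}
        )
        obj_id += 1

    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    x = (cc + c_lo).ravel() * spec.pitch
    y = (rr + r_lo).ravel() * spec.pitch
    flat_labels = labels.ravel()
    flat_ids = obj_ids.ravel()

    def with_noise(z_flat: np.ndarray) -> np.ndarray:
        pts = np.column_stack([x, y, z_flat])
        if spec.sigma_x > 0:
            pts[:, 0] = pts[:, 0] + rng.normal(0.0, spec.sigma_x, len(pts))
        if spec.sigma_z > 0:
            pts[:, 2] = pts[:, 2] + rng.normal(0.0, spec.sigma_z, len(pts))
        return pts

    upper_pts = with_noise(z_up.ravel())
    lower_pts = with_noise(z_lo_buf.ravel())
    # calibrated lower frame: gauge surfaces coincide, then inject misalignment
    if spec.gauge is not None:
        lower_pts[:, 2] += spec.gauge.thickness
    offset = np.asarray(spec.lower_offset, dtype=np.float64)
    lower_pts -= offset

    upper = LabeledPointCloud(upper_pts, flat_labels, "upper")
    lower = LabeledPointCloud(lower_pts, flat_labels.copy(), "lower")
    truth = SceneTruth(
        objects=pd.DataFrame(records),
        lower_offset=offset,
        upper_object_ids=flat_ids,
        lower_object_ids=flat_ids.copy(),
    )
    return upper, lower, truth


def toy_segmentation_scenes(
    n_scenes: int = 6, n_points: int = 512, seed: int = 0
) -> list[LabeledPointCloud]:
    """Small labeled training scenes for desk-scale network runs.

    Each scene is a flat background sheet (label 4) plus four compact
    clusters, one per shred class, at well-separated locations with
    positional jitter — spatially separable classes that a working
    segmentation network must learn quickly.  Not a substitute for real
    scan texture; see the synthetic scene generator for geometry.
    """
    rng = np.random.default_rng(seed)
    anchors = np.array([[2.0, 2.0], [8.0, 2.0], [2.0, 8.0], [8.0, 8.0]])
    scenes = []
    for _ in range(n_scenes):
        n_bg = n_points // 3
        n_cls = (n_points - n_bg) // 4
        pts = [np.column_stack([rng.uniform(0, 10, n_bg), rng.uniform(0, 10, n_bg),
                                rng.normal(0.0, 0.02, n_bg)])]
        labels = [np.full(n_bg, BACKGROUND_LABEL)]
        for c in range(4):
            center = anchors[c] + rng.uniform(-0.5, 0.5, 2)
            n_c = n_cls if c < 3 else n_points - n_bg - 3 * n_cls
            xy = center + rng.normal(0.0, 0.6, (n_c, 2))
            z = 0.5 + rng.normal(0.0, 0.05, n_c)
            pts.append(np.column_stack([xy, z]))
            labels.append(np.full(n_c, c))
        scenes.append(
            LabeledPointCloud(np.vstack(pts), np.concatenate(labels), "upper")
        )
    return scenes
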