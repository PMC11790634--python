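"""Core data types and file I/O for height maps and labeled point clouds.

A line-scan profilometer produces a *height map*: a rectangular grid of
sensor counts, one per (row, column) scan position, with a fixed physical
pitch along each axis.  Converting counts to millimetres and grid indices
to physical coordinates yields a point cloud.  Points carry an integer
class label::

    0  cut stem
    1  tobacco silk
    2  reconstituted tobacco shred
    3  expanded tobacco silk
    4  background / noise

Clouds are tagged with the surface they were scanned from (``upper`` or
``lower``); the two surfaces never overlap, which is why registration via
a reference gauge block exists downstream.

Supported on-disk formats: PLY (ascii and binary little-endian, with a
custom integer ``label`` property) and whitespace-delimited
``x y z label`` text with ``#`` comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

VALID_LABELS = frozenset(range(5))
BACKGROUND_LABEL = 4
CLASS_NAMES = {
    0: "cut stem",
    1: "tobacco silk",
    2: "reconstituted tobacco shred",
    3: "expanded tobacco silk",
    4: "background noise",
}


class CloudFormatError(ValueError):
    """Raised for malformed cloud files (bad rows, unknown labels, ...)."""


@dataclass
class HeightMap:
    """Raw scanner output: a 2-D grid of height counts.

    Parameters
    ----------
    values
        2-D array of height counts (sensor units).  Rows advance along
        the scan (y) direction, columns along the profile (x) direction.
    x_pitch, y_pitch
        Physical spacing in mm per column / per row; must be positive.
    invalid_value
        Sentinel marking no-return pixels.  NaN entries are always
        treated as invalid as well.
    """

    values: np.ndarray
    x_pitch: float
    y_pitch: float
    invalid_value: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("height map must be a non-empty 2-D matrix")
        if not (self.x_pitch > 0 and self.y_pitch > 0):
            raise ValueError("pitches must be > 0")

    @property
    def valid_mask(self) -> np.ndarray:
        mask = ~np.isnan(self.values)
        if not np.isnan(self.invalid_value):
            mask &= self.values != self.invalid_value
        return mask


@dataclass
class LabeledPointCloud:
    """Points in mm with parallel integer class labels and a surface tag."""

    points: np.ndarray
    labels: np.ndarray
    surface: str = "upper"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if len(self.labels) != len(self.points):
            raise ValueError("labels must be parallel to points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"labels outside 0..4: {sorted(bad)}")
        if self.surface not in ("upper", "lower"):
            raise ValueError("surface must be 'upper' or 'lower'")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "LabeledPointCloud":
        """Sub-cloud for a boolean mask or index array, order preserved."""
        return LabeledPointCloud(self.points[mask], self.labels[mask], self.surface)

    def translated(self, offset: Sequence[float]) -> "LabeledPointCloud":
        return LabeledPointCloud(
            self.points + np.asarray(offset, dtype=np.float64), self.labels, self.surface
        )

    def copy(self) -> "LabeledPointCloud":
        return LabeledPointCloud(self.points.copy(), self.labels.copy(), self.surface)


@dataclass
class ShredInstance:
    """One segmented shred: its class and its per-surface point sets."""

    class_label: int
    upper_points: np.ndarray
    lower_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        if self.class_label not in range(4):
            raise ValueError("class_label must be a shred class (0..3)")
        self.upper_points = np.atleast_2d(np.asarray(self.upper_points, dtype=np.float64))
        self.lower_points = np.atleast_2d(np.asarray(self.lower_points, dtype=np.float64))
        if self.lower_points.size == 0:
            self.lower_points = self.lower_points.reshape(0, 3)
        if self.upper_points.size == 0:
            raise ValueError("upper_points must be nonempty")


def heightmap_to_cloud(
    hm: HeightMap, count_to_mm: float, surface: str = "upper"
) -> LabeledPointCloud:
    """Convert a height map to a point cloud.

    One point per valid pixel at ``(col * x_pitch, row * y_pitch,
    value * count_to_mm)``; grid indices are 0-based with the origin at
    the grid corner.  All labels are initialised to background (4).
    """
    if count_to_mm <= 0:
        raise ValueError("count_to_mm must be > 0")
    mask = hm.valid_mask
    rows, cols = np.nonzero(mask)
    pts = np.column_stack(
        [
            cols * hm.x_pitch,
            rows * hm.y_pitch,
            hm.values[rows, cols] * count_to_mm,
        ]
    )
    labels = np.full(len(pts), BACKGROUND_LABEL, dtype=np.int64)
    return LabeledPointCloud(pts, labels, surface)


# ---------------------------------------------------------------------------
# delimited-text cloud format: "x y z label", '#' comments


def _read_cloud_text(path: Path) -> LabeledPointCloud:
    pts: list[tuple[float, float, float]] = []
    labels: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            fields = body.split()
            if len(fields) != 4:
                raise CloudFormatError(
                    f"{path}:{lineno}: expected 4 fields 'x y z label', got {len(fields)}"
                )
            try:
                x, y, z = (float(v) for v in fields[:3])
                lab = int(fields[3])
            except ValueError as exc:
                raise CloudFormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if lab not in VALID_LABELS:
                raise CloudFormatError(f"{path}:{lineno}: unknown label code {lab}")
            pts.append((x, y, z))
            labels.append(lab)
    return LabeledPointCloud(np.asarray(pts, dtype=np.float64).reshape(-1, 3), labels)


def _write_cloud_text(cloud: LabeledPointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z label\n")
        for (x, y, z), lab in zip(cloud.points, cloud.labels):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {lab}\n")


# ---------------------------------------------------------------------------
# PLY with a custom integer 'label' property

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "short": "i2", "ushort": "u2",
    "int": "i4", "uint": "u4", "float": "f4", "double": "f8",
    "int8": "i1", "uint8": "u1", "int16": "i2", "uint16": "u2",
    "int32": "i4", "uint32": "u4", "float32": "f4", "float64": "f8",
}


def _read_cloud_ply(path: Path) -> LabeledPointCloud:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise CloudFormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise CloudFormatError(f"{path}: unexpected end of header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise CloudFormatError(f"{path}: list properties unsupported for vertices")
                props.append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise CloudFormatError(f"{path}: no vertex element")
        names = [name for name, _ in props]
        for req in ("x", "y", "z", "label"):
            if req not in names:
                raise CloudFormatError(f"{path}: missing vertex property {req!r}")
        if fmt == "ascii":
            rows = np.loadtxt(fh, dtype=np.float64, max_rows=n_vertex, ndmin=2)
            if rows.shape != (n_vertex, len(props)):
                raise CloudFormatError(f"{path}: vertex data shape mismatch")
            data = {name: rows[:, i] for i, (name, _) in enumerate(props)}
        else:
            dtype = np.dtype([(name, "<" + code) for name, code in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) != dtype.itemsize * n_vertex:
                raise CloudFormatError(f"{path}: truncated binary vertex data")
            arr = np.frombuffer(raw, dtype=dtype)
            data = {name: arr[name] for name, _ in props}
    labels = np.asarray(data["label"])
    if not np.allclose(labels, np.round(labels)):
        raise CloudFormatError(f"{path}: non-integer label values")
    labels = np.round(labels).astype(np.int64)
    bad = set(np.unique(labels)) - VALID_LABELS if len(labels) else set()
    if bad:
        raise CloudFormatError(f"{path}: unknown label codes {sorted(bad)}")
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    return LabeledPointCloud(pts.reshape(-1, 3), labels)


def _write_cloud_ply(cloud: LabeledPointCloud, path: Path, binary: bool) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {len(cloud)}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        "property uchar label\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            dtype = np.dtype([("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("label", "u1")])
            arr = np.empty(len(cloud), dtype=dtype)
            arr["x"], arr["y"], arr["z"] = cloud.points.T
            arr["label"] = cloud.labels
            fh.write(arr.tobytes())
        else:
            for (x, y, z), lab in zip(cloud.points, cloud.labels):
                fh.write(f"{x:.17g} {y:.17g} {z:.17g} {lab}\n".encode("ascii"))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "ply" if path.suffix.lower() == ".ply" else "xyz"


def read_cloud(path: str | Path, format: str | None = None) -> LabeledPointCloud:
    """Read a labeled cloud; format 'ply' or 'xyz' (inferred from suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_cloud_ply(path)
    if fmt == "xyz":
        return _read_cloud_text(path)
    raise ValueError(f"unknown cloud format {fmt!r}")


def write_cloud(
    cloud: LabeledPointCloud,
    path: str | Path,
    format: str | None = None,
    binary: bool = False,
) -> None:
    """Write a labeled cloud.  write ∘ read is identity on labels and
    coordinates (to float round-trip precision)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_cloud_ply(cloud, path, binary)
    elif fmt == "xyz":
        _write_cloud_text(cloud, path)
    else:
        raise ValueError(f"unknown cloud format {fmt!r}")


# ---------------------------------------------------------------------------
# height-map text I/O: '# key value' header lines, then a delimited matrix


def write_heightmap(hm: HeightMap, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# x_pitch {hm.x_pitch:.9g}\n")
        fh.write(f"# y_pitch {hm.y_pitch:.9g}\n")
        fh.write(f"# invalid_value {hm.invalid_value!r}\n".replace("'", ""))
        np.savetxt(fh, hm.values, fmt="%.9g")


def read_heightmap(path: str | Path) -> HeightMap:
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2:
                meta[parts[0]] = float(parts[1])
        elif line.strip():
            data_lines.append(line)
    values = np.loadtxt(data_lines, ndmin=2)
    return HeightMap(
        values,
        x_pitch=meta.get("x_pitch", 1.0),
        y_pitch=meta.get("y_pitch", 1.0),
        invalid_value=meta.get("invalid_value", float("nan")),
    )
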