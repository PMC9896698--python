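"""Point-cloud container and file I/O.

A :class:`PointCloud` holds metric (cm) coordinates of a reconstructed root
system with optional per-point RGB color.  The canonical frame has the plant
base at the top and growth along the negative z axis; ``frame_oriented``
records that the up-vector convention has been applied.

Supported formats: PLY (ascii and binary little-endian, via trimesh), plain
whitespace XYZ[RGB] text, and ASCII PCD v0.7.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from .errors import CloudFormatError, EmptyCloudError

__all__ = ["PointCloud", "load_cloud", "save_cloud"]


@dataclass
class PointCloud:
    """N metric 3D points with optional per-point RGB color.

    Parameters
    ----------
    points : (N, 3) float array, coordinates in cm.
    colors : optional (N, 3) uint8 array, one RGB triple per point.
    frame_oriented : True once the up-vector convention (growth along -z)
        has been applied.
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    frame_oriented: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise CloudFormatError(
                f"points must be (N, 3), got {self.points.shape}"
            )
        if self.points.shape[0] == 0:
            raise EmptyCloudError("point cloud contains no points")
        if not np.isfinite(self.points).all():
            raise CloudFormatError("point coordinates must all be finite")
        if self.colors is not None:
            self.colors = np.asarray(self.colors)
            if self.colors.shape != (len(self.points), 3):
                raise CloudFormatError(
                    "colors must have exactly one (r, g, b) triple per point; "
                    f"got {self.colors.shape} for {len(self.points)} points"
                )
            self.colors = self.colors.astype(np.uint8)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, mask_or_idx) -> "PointCloud":
        """Subset of points (order preserved), carrying colors along."""
        pts = self.points[mask_or_idx]
        cols = self.colors[mask_or_idx] if self.has_colors else None
        return PointCloud(pts, cols, frame_oriented=self.frame_oriented)

    def with_points(self, points: np.ndarray, **kw) -> "PointCloud":
        return replace(self, points=points, **kw)


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "xyz", "pcd"):
        return suffix
    if suffix == "txt":
        return "xyz"
    raise CloudFormatError(f"cannot infer format from suffix of '{path}'")


def load_cloud(path, format: str = "auto") -> PointCloud:
    """Read a point cloud from PLY / XYZ / PCD.

    All points (and colors if present) are returned in file order with no
    filtering applied.
    """
    path = Path(path)
    if not path.exists():
        raise CloudFormatError(f"file not found: {path}")
    fmt = _detect_format(path, format)
    if fmt == "ply":
        return _load_ply(path)
    if fmt == "xyz":
        return _load_xyz(path)
    if fmt == "pcd":
        return _load_pcd(path)
    raise CloudFormatError(f"unsupported format '{fmt}'")


def save_cloud(cloud: PointCloud, path, format: str = "auto",
               binary: bool = True) -> None:
    """Write a point cloud to PLY / XYZ / PCD."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "ply":
        _save_ply(cloud, path, binary=binary)
    elif fmt == "xyz":
        _save_xyz(cloud, path)
    elif fmt == "pcd":
        _save_pcd(cloud, path)
    else:
        raise CloudFormatError(f"unsupported format '{fmt}'")


# ---------------------------------------------------------------- PLY


def _load_ply(path: Path) -> PointCloud:
    try:
        obj = trimesh.load(str(path), file_type="ply", process=False)
    except EmptyCloudError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise CloudFormatError(f"unreadable PLY file '{path}': {exc}") from exc
    verts = np.asarray(obj.vertices, dtype=np.float64)
    if verts.size == 0:
        raise EmptyCloudError(f"PLY file '{path}' contains no vertices")
    colors = None
    raw = None
    if isinstance(obj, trimesh.PointCloud):
        try:
            raw = np.asarray(obj.colors)
        except Exception:  # trimesh raises when no colors stored
            raw = None
    elif hasattr(obj, "visual") and hasattr(obj.visual, "vertex_colors"):
        raw = np.asarray(obj.visual.vertex_colors)
    if raw is not None and raw.ndim == 2 and len(raw) == len(verts):
        rgb = raw[:, :3].astype(np.uint8)
        # trimesh substitutes an all-gray default when the file had no color
        if not (rgb == rgb[0]).all() or _ply_declares_color(path):
            colors = rgb
    return PointCloud(verts, colors)


def _ply_declares_color(path: Path) -> bool:
    with open(path, "rb") as fh:
        header = fh.read(4096).split(b"end_header")[0]
    return b"red" in header


def _save_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    colors = None
    if cloud.has_colors:
        colors = np.column_stack(
            [cloud.colors, np.full(len(cloud), 255, dtype=np.uint8)]
        )
    pc = trimesh.PointCloud(cloud.points, colors=colors)
    pc.export(str(path), encoding="binary" if binary else "ascii")


# ---------------------------------------------------------------- XYZ


def _load_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 6):
                raise CloudFormatError(
                    f"'{path}' line {lineno}: expected 3 or 6 columns, "
                    f"got {len(parts)}: {line!r}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise CloudFormatError(
                    f"'{path}' line {lineno}: non-numeric value in {line!r}"
                ) from exc
    if not rows:
        raise EmptyCloudError(f"XYZ file '{path}' contains no points")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise CloudFormatError(f"'{path}': mixed 3- and 6-column records")
    arr = np.asarray(rows, dtype=np.float64)
    colors = arr[:, 3:6].astype(np.uint8) if arr.shape[1] == 6 else None
    return PointCloud(arr[:, :3], colors)


def _save_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        if cloud.has_colors:
            for p, c in zip(cloud.points, cloud.colors):
                fh.write(
                    f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g} {c[0]} {c[1]} {c[2]}\n"
                )
        else:
            for p in cloud.points:
                fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")


# ---------------------------------------------------------------- PCD


def _load_pcd(path: Path) -> PointCloud:
    """ASCII PCD v0.7 with fields x y z plus optional rgb or r g b."""
    fields = []
    n_points = None
    data_start = None
    lines = path.read_text().splitlines()
    for i, line in enumerate(lines):
        token = line.split("#")[0].strip()
        if not token:
            continue
        key, *rest = token.split()
        key = key.upper()
        if key == "FIELDS":
            fields = [f.lower() for f in rest]
        elif key == "POINTS":
            n_points = int(rest[0])
        elif key == "DATA":
            if rest and rest[0].lower() != "ascii":
                raise CloudFormatError(
                    f"'{path}': only DATA ascii PCD is supported, got {rest}"
                )
            data_start = i + 1
            break
    if data_start is None or not fields:
        raise CloudFormatError(f"'{path}': missing PCD header (FIELDS/DATA)")
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise CloudFormatError(f"'{path}': PCD missing field '{axis}'")
    idx = {f: j for j, f in enumerate(fields)}
    pts, cols = [], []
    packed_rgb = "rgb" in idx
    separate_rgb = all(c in idx for c in ("r", "g", "b"))
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise CloudFormatError(
                f"'{path}' line {lineno}: expected {len(fields)} values, "
                f"got {len(parts)}"
            )
        try:
            pts.append([float(parts[idx[a]]) for a in ("x", "y", "z")])
            if packed_rgb:
                cols.append(_unpack_rgb(float(parts[idx["rgb"]])))
            elif separate_rgb:
                cols.append([int(float(parts[idx[c]])) for c in "rgb"])
        except (ValueError, struct.error) as exc:
            raise CloudFormatError(
                f"'{path}' line {lineno}: bad record {line!r}"
            ) from exc
    if not pts:
        raise EmptyCloudError(f"PCD file '{path}' contains no points")
    if n_points is not None and n_points != len(pts):
        raise CloudFormatError(
            f"'{path}': header declares {n_points} points, found {len(pts)}"
        )
    colors = np.asarray(cols, dtype=np.uint8) if cols else None
    return PointCloud(np.asarray(pts), colors)


def _unpack_rgb(value: float):
    packed = struct.unpack("I", struct.pack("f", value))[0]
    return [(packed >> 16) & 0xFF, (packed >> 8) & 0xFF, packed & 0xFF]


def _pack_rgb(r: int, g: int, b: int) -> float:
    packed = (int(r) << 16) | (int(g) << 8) | int(b)
    return struct.unpack("f", struct.pack("I", packed))[0]


def _save_pcd(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    with_color = cloud.has_colors
    fields = "x y z rgb" if with_color else "x y z"
    size = "4 4 4 4" if with_color else "4 4 4"
    types = "F F F F" if with_color else "F F F"
    count = "1 1 1 1" if with_color else "1 1 1"
    with open(path, "w") as fh:
        fh.write(
            "# .PCD v0.7 - Point Cloud Data file format\n"
            "VERSION 0.7\n"
            f"FIELDS {fields}\nSIZE {size}\nTYPE {types}\nCOUNT {count}\n"
            f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\n"
            f"POINTS {n}\nDATA ascii\n"
        )
        if with_color:
            for p, c in zip(cloud.points, cloud.colors):
                fh.write(
                    f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g} "
                    f"{_pack_rgb(*c):.8g}\n"
                )
        else:
            for p in cloud.points:
                fh.write(f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}\n")
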