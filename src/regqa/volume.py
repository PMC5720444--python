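"""Volumetric data model, axis-aligned geometry, and standard-format I/O.

All images in this package are 3D scalar volumes on an axis-aligned grid.
Conventions (fixed throughout):

* voxel indices are 0-based triples ``(i, j, k)`` with axes ordered
  ``(x, y, z)`` and ``z`` the slice axis;
* the physical position (mm) of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (voxel-center convention);
* oblique headers (non-diagonal direction matrices) are rejected rather
  than silently ignored, because ignoring a rotation would corrupt every
  millimetre distance downstream.

Supported on-disk formats are NIfTI-1 (via nibabel) and NRRD (via
SimpleITK).  Binary masks are written as unsigned 8-bit 0/1 volumes.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("regqa")

MODALITIES = ("CT", "MRI", "PET", "MVCT", "GRID", "MASK", "OTHER")


class GeometryMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class FrameGeometry:
    """Shape, spacing and origin of an axis-aligned voxel grid.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``.
    spacing
        Voxel spacing in mm, all components strictly positive.
    origin
        Physical position (mm) of voxel ``(0, 0, 0)`` (voxel center).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("expected 3D volume geometry")
        if any(s <= 0 for s in shape):
            raise ValueError(f"degenerate shape {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be strictly positive, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def bbox_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box (lo, hi) of the volume, including the
        half-voxel border around the outermost voxel centers."""
        o = np.asarray(self.origin, float)
        sp = np.asarray(self.spacing, float)
        n = np.asarray(self.shape, float)
        return o - 0.5 * sp, o + (n - 0.5) * sp

    @property
    def center_bbox_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box spanned by voxel centers only."""
        o = np.asarray(self.origin, float)
        sp = np.asarray(self.spacing, float)
        n = np.asarray(self.shape, float)
        return o, o + (n - 1.0) * sp

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, float) * np.asarray(self.spacing, float)

    def index_to_physical(self, idx: Sequence[int]) -> np.ndarray:
        idx = np.asarray(idx)
        if idx.shape[-1] != 3:
            raise ValueError("index must be a triple")
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise IndexError(f"index {idx.tolist()} out of range for shape {self.shape}")
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, p: Sequence[float]) -> np.ndarray:
        """Nearest voxel index for a physical point (inverse of
        :meth:`index_to_physical` on valid indices)."""
        p = np.asarray(p, float)
        idx = np.rint((p - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise IndexError(f"point {p.tolist()} maps outside the volume")
        return idx

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center positions as an ``(nx, ny, nz, 3)`` array (mm)."""
        ax = [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack(g, axis=-1)


@dataclass
class Volume:
    """A 3D scalar image with geometry and a modality tag.

    ``meta`` is free-form provenance (e.g. the true transform attached to a
    synthetic image so mock systems can replay it); it never participates in
    equality or I/O round-trips.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "OTHER"
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        if self.data.size == 0:
            raise ValueError("empty-shape volume")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        # geometry validation is delegated to FrameGeometry
        g = FrameGeometry(self.data.shape, self.spacing, self.origin)
        self.spacing = g.spacing
        self.origin = g.origin

    @property
    def geometry(self) -> FrameGeometry:
        return FrameGeometry(self.data.shape, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def same_geometry(self, other: "Volume | BinaryMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == tuple(other.data.shape)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class BinaryMask:
    """Per-voxel boolean region of interest on a Volume grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D data")
        g = FrameGeometry(self.data.shape, self.spacing, self.origin)
        self.spacing = g.spacing
        self.origin = g.origin

    @property
    def geometry(self) -> FrameGeometry:
        return FrameGeometry(self.data.shape, self.spacing, self.origin)

    @property
    def volume_mm3(self) -> float:
        return float(self.data.sum()) * self.geometry.voxel_volume_mm3

    def to_volume(self) -> Volume:
        """Binary image with intensity exactly 1 inside and 0 outside."""
        return Volume(self.data.astype(np.uint8), self.spacing, self.origin, modality="MASK")


@dataclass
class PointSet:
    """Labeled physical-coordinate (mm) points inside a volume frame.

    Labels are unique integers; every point must lie within the physical
    bounding box of ``frame`` (construction rejects violations).
    """

    points: np.ndarray
    labels: np.ndarray
    frame: FrameGeometry

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.labels = np.asarray(self.labels, int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of mm coordinates")
        if self.labels.shape != (self.points.shape[0],):
            raise ValueError("labels must match the number of points")
        if len(np.unique(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        lo, hi = self.frame.bbox_mm
        if np.any(self.points < lo - 1e-9) or np.any(self.points > hi + 1e-9):
            raise ValueError("points must lie within the physical bounding box of the frame")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# I/O


def _infer_format(path: os.PathLike | str) -> str:
    name = str(path).lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    raise ValueError(f"cannot infer volume format from path {path!r}")


def read_volume(path: os.PathLike | str, format: str = "auto", modality: str = "OTHER") -> Volume:
    """Read a NIfTI or NRRD volume, preserving spacing and origin.

    Intensities are returned unmodified (no scaling); only axis-aligned
    geometries are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read volume: no such file {path}")
    fmt = _infer_format(path) if format == "auto" else format
    if fmt == "nifti":
        return _read_nifti(path, modality)
    if fmt == "nrrd":
        return _read_nrrd(path, modality)
    raise ValueError(f"unknown format {fmt!r}")


def _read_nifti(path: Path, modality: str) -> Volume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise ValueError(f"oblique/rotated NIfTI geometry in {path} is not supported")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError(f"missing or invalid spacing in NIfTI header of {path}")
    origin = aff[:3, 3]
    return Volume(data, tuple(spacing), tuple(origin), modality=modality)


def _read_nrrd(path: Path, modality: str) -> Volume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:
        raise IOError(f"unreadable NRRD file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"expected 3D volume, got {img.GetDimension()}D in {path}")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(f"oblique NRRD geometry in {path} is not supported")
    spacing = np.asarray(img.GetSpacing(), float)
    if np.any(spacing <= 0):
        raise ValueError(f"missing or invalid spacing in NRRD header of {path}")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    return Volume(data, tuple(spacing), tuple(img.GetOrigin()), modality=modality)


def write_volume(v: Volume | BinaryMask, path: os.PathLike | str, format: str | None = None) -> Path:
    """Write a volume (or mask, encoded 0/1 uint8) to NIfTI or NRRD.

    The written file re-reads to a volume with bit-identical data and
    geometry equal to 1e-6 mm.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"cannot write volume: parent directory {path.parent} does not exist")
    if isinstance(v, BinaryMask):
        v = v.to_volume()
    fmt = _infer_format(path) if format is None else format
    if fmt == "nifti":
        import nibabel as nib

        aff = np.eye(4)
        aff[:3, :3] = np.diag(v.spacing)
        aff[:3, 3] = v.origin
        img = nib.Nifti1Image(v.data, aff)
        img.header.set_data_dtype(v.data.dtype)
        nib.save(img, str(path))
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in v.spacing))
        img.SetOrigin(tuple(float(o) for o in v.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def index_to_physical(v: Volume | BinaryMask | FrameGeometry, idx: Sequence[int]) -> np.ndarray:
    g = v if isinstance(v, FrameGeometry) else v.geometry
    return g.index_to_physical(idx)


def physical_to_index(v: Volume | BinaryMask | FrameGeometry, p: Sequence[float]) -> np.ndarray:
    g = v if isinstance(v, FrameGeometry) else v.geometry
    return g.physical_to_index(p)


# ---------------------------------------------------------------------------
# Contour rasterization


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for two open segments (shared endpoints do
    not count)."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _polygon_self_intersects(poly: np.ndarray) -> bool:
    n = len(poly)
    for i in range(n):
        a1, a2 = poly[i], poly[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            if _segments_intersect(a1, a2, poly[j], poly[(j + 1) % n]):
                return True
    return False


def points_in_polygon(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray-crossing) interior test.

    Strict interior: points exactly on an edge resolve by the half-open
    crossing convention, so results are deterministic under translation.
    """
    px = np.asarray(px, float)
    py = np.asarray(py, float)
    poly = np.asarray(poly, float)
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    inside = np.zeros(px.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        if not np.any(crosses):
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_contours(
    slices: Iterable[tuple[int, np.ndarray]],
    frame: FrameGeometry,
) -> BinaryMask:
    """Rasterize per-slice closed polygons (mm, in-plane) into a binary mask.

    A voxel is set when its center is inside any polygon of its slice by
    the even-odd rule.  Self-intersecting polygons are rasterized anyway
    (even-odd still applies) with a logged warning.
    """
    data = np.zeros(frame.shape, dtype=bool)
    xs = frame.origin[0] + np.arange(frame.shape[0]) * frame.spacing[0]
    ys = frame.origin[1] + np.arange(frame.shape[1]) * frame.spacing[1]
    px, py = np.meshgrid(xs, ys, indexing="ij")
    for k, poly in slices:
        k = int(k)
        if not (0 <= k < frame.shape[2]):
            raise IndexError(f"contour slice {k} out of range for frame with {frame.shape[2]} slices")
        poly = np.asarray(poly, float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("each contour must be an (n>=3, 2) array of in-plane mm points")
        closed = poly[:-1] if np.allclose(poly[0], poly[-1]) else poly
        if _polygon_self_intersects(closed):
            logger.warning("self-intersecting polygon on slice %d; even-odd rule applied", k)
        data[:, :, k] |= points_in_polygon(px, py, poly)
    return BinaryMask(data, frame.spacing, frame.origin)


def read_contours(path: os.PathLike | str) -> list[tuple[int, np.ndarray]]:
    """Read contour slices from JSON: {"slices": [{"k": int, "points_mm": [[x, y], ...]}, ...]}."""
    with open(path) as fh:
        doc = json.load(fh)
    return [(int(s["k"]), np.asarray(s["points_mm"], float)) for s in doc["slices"]]


def write_contours(slices: Iterable[tuple[int, np.ndarray]], path: os.PathLike | str) -> Path:
    doc = {"slices": [{"k": int(k), "points_mm": np.asarray(p, float).tolist()} for k, p in slices]}
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path
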