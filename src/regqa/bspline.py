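"""Cubic B-spline free-form deformations and displacement-error arithmetic.

A transform is a tensor-product cubic B-spline over a regular control-point
grid, storing a 3-component mm displacement coefficient per control point.
The convention is *forward* everywhere: a material point at position ``p``
moves to ``p + displacement(p)``.  Dense images are warped by numerically
inverting this forward map (fixed-point iteration) and resampling
backward; sparse grid-probe images are instead forward-splatted (see
:mod:`regqa.gridprobe`).

The displacement error (DE) between a true deformation and a recovered one
is the RMS, over sampled points, of the residual displacement magnitude;
the axial DE is the same RMS restricted to the in-plane (x, y) components.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import FrameGeometry, PointSet, Volume

_CHUNK = 1 << 18  # points per evaluation block (bounds the 64-neighbor gather)


class ConvergenceError(RuntimeError):
    """Numerical inversion of a forward map failed to converge."""


def _cubic_weights(u: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline basis values for local coordinates u in [0, 1).

    Returns an (n, 4) array of the weights applied to control points
    i-1 .. i+2 around the containing cell i.  Rows sum to 1 (partition of
    unity).
    """
    u = np.asarray(u, float)
    u2 = u * u
    u3 = u2 * u
    w = np.empty(u.shape + (4,), float)
    w[..., 0] = (1.0 - u) ** 3 / 6.0
    w[..., 1] = (3.0 * u3 - 6.0 * u2 + 4.0) / 6.0
    w[..., 2] = (-3.0 * u3 + 3.0 * u2 + 3.0 * u + 1.0) / 6.0
    w[..., 3] = u3 / 6.0
    return w


@dataclass
class BSplineTransform:
    """Forward cubic B-spline displacement field.

    Parameters
    ----------
    control_origin
        Physical position (mm) of control point (0, 0, 0).
    control_spacing
        Control-grid spacing (mm), strictly positive.
    coefficients
        ``(mx, my, mz, 3)`` array of mm displacement coefficients.
    """

    control_origin: np.ndarray
    control_spacing: np.ndarray
    coefficients: np.ndarray

    degree: int = field(default=3, init=False)

    def __post_init__(self):
        self.control_origin = np.asarray(self.control_origin, float).reshape(3)
        self.control_spacing = np.asarray(self.control_spacing, float).reshape(3)
        if np.any(self.control_spacing <= 0):
            raise ValueError("control spacing must be strictly positive")
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (mx, my, mz, 3)")
        if min(self.coefficients.shape[:3]) < 4:
            raise ValueError("need at least 4 control points per axis for a cubic spline")

    # -- support ----------------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]

    @property
    def support_lo(self) -> np.ndarray:
        """Lowest point with full cubic support (one spacing inside the grid)."""
        return self.control_origin + self.control_spacing

    @property
    def support_hi(self) -> np.ndarray:
        m = np.asarray(self.grid_shape, float)
        return self.control_origin + (m - 2.0) * self.control_spacing

    def covers(self, frame: FrameGeometry, margin: float = 0.0) -> bool:
        lo, hi = frame.center_bbox_mm
        return bool(np.all(self.support_lo <= lo - margin) and np.all(self.support_hi >= hi + margin))

    # -- evaluation -------------------------------------------------------
    def displacement_at(self, points: np.ndarray, clip: bool = False) -> np.ndarray:
        """Tensor-product cubic interpolation of the coefficient grid.

        ``clip`` clamps points to the support box instead of raising; it is
        used internally by the fixed-point inverter, which may step slightly
        outside the support mid-iteration.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        if pts.shape[1] != 3:
            raise ValueError("points must be (n, 3) mm coordinates")
        if clip:
            pts = np.clip(pts, self.support_lo, self.support_hi)
        elif np.any(pts < self.support_lo - 1e-9) or np.any(pts > self.support_hi + 1e-9):
            raise ValueError("point outside the B-spline support; no extrapolation")
        out = np.empty_like(pts)
        for s in range(0, len(pts), _CHUNK):
            out[s : s + _CHUNK] = self._eval_block(pts[s : s + _CHUNK])
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def _eval_block(self, pts: np.ndarray) -> np.ndarray:
        t = (pts - self.control_origin) / self.control_spacing
        i = np.floor(t).astype(int)
        m = np.asarray(self.grid_shape)
        # clamp the cell so i-1 .. i+2 stays in-grid (points at the exact
        # support boundary land on the edge cell)
        i = np.clip(i, 1, m - 3)
        u = t - i
        w = [_cubic_weights(u[:, a]) for a in range(3)]  # each (n, 4)
        off = np.arange(-1, 3)
        ix = i[:, 0, None] + off
        iy = i[:, 1, None] + off
        iz = i[:, 2, None] + off
        patch = self.coefficients[
            ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :]
        ]  # (n, 4, 4, 4, 3)
        return np.einsum("na,nb,nc,nabcd->nd", w[0], w[1], w[2], patch, optimize=True)

    def displacement_field(self, frame: FrameGeometry, x_chunk: int | None = None) -> np.ndarray:
        """Dense displacement field at every voxel center of ``frame``.

        Uses the separable structure of the tensor product: one basis
        matrix per axis contracted against the coefficient grid, which is
        far cheaper than scattered evaluation on a full grid.
        """
        Bx, By, Bz = (self._axis_basis(frame, a) for a in range(3))
        a1 = np.tensordot(Bz, self.coefficients, axes=(1, 2))  # (nz, mx, my, 3)
        a2 = np.tensordot(By, a1, axes=(1, 2))  # (ny, nz, mx, 3)
        out = np.tensordot(Bx, a2, axes=(1, 2))  # (nx, ny, nz, 3)
        return out

    def _axis_basis(self, frame: FrameGeometry, axis: int) -> np.ndarray:
        x = frame.origin[axis] + np.arange(frame.shape[axis]) * frame.spacing[axis]
        t = (x - self.control_origin[axis]) / self.control_spacing[axis]
        i = np.clip(np.floor(t).astype(int), 1, self.grid_shape[axis] - 3)
        u = t - i
        w = _cubic_weights(u)
        B = np.zeros((len(x), self.grid_shape[axis]))
        for c in range(4):
            B[np.arange(len(x)), i - 1 + c] = w[:, c]
        return B

    # -- algebra ----------------------------------------------------------
    def inverse(self) -> "NumericalInverse":
        return NumericalInverse(self)

    def scaled(self, factor: float) -> "BSplineTransform":
        return scale_transform(self, factor)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "control_origin": self.control_origin.tolist(),
            "control_spacing": self.control_spacing.tolist(),
            "grid_shape": list(self.grid_shape),
            "coefficients": self.coefficients.tolist(),
            "convention": "forward_mm",
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BSplineTransform":
        if doc.get("convention", "forward_mm") != "forward_mm":
            raise ValueError(f"unsupported transform convention {doc.get('convention')!r}")
        coeff = np.asarray(doc["coefficients"], float)
        if list(coeff.shape[:3]) != list(doc["grid_shape"]):
            raise ValueError("grid_shape does not match coefficient array")
        return cls(doc["control_origin"], doc["control_spacing"], coeff)

    def save(self, path: os.PathLike | str) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)
        return path

    @classmethod
    def load(cls, path: os.PathLike | str) -> "BSplineTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class UniformTranslation:
    """Constant displacement everywhere; handy as an injected mock residual."""

    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, float).reshape(3)

    def displacement_at(self, points: np.ndarray, clip: bool = False) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = np.broadcast_to(self.vector, pts.shape).copy()
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def inverse(self) -> "UniformTranslation":
        return UniformTranslation(-self.vector)


@dataclass
class ComposedTransform:
    """Apply ``first`` then ``second`` (forward composition).

    displacement(p) = d1(p) + d2(p + d1(p))
    """

    first: object
    second: object

    def displacement_at(self, points: np.ndarray, clip: bool = False) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        d1 = self.first.displacement_at(pts, clip=clip)
        d2 = self.second.displacement_at(pts + d1, clip=clip)
        out = d1 + d2
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def inverse(self) -> "ComposedTransform":
        return ComposedTransform(_inverse_of(self.second), _inverse_of(self.first))


@dataclass
class NumericalInverse:
    """Numerically inverted forward map.

    ``displacement_at(y)`` returns ``x - y`` where ``x`` solves
    ``x + d_forward(x) = y`` by fixed-point iteration, to ``tol`` mm in at
    most ``max_iter`` sweeps.  The fraction of non-converged points from
    the most recent evaluation is kept on ``last_unconverged_fraction``.
    """

    forward: object
    tol: float = 0.01
    max_iter: int = 20

    last_unconverged_fraction: float = field(default=0.0, init=False, compare=False)

    def displacement_at(
        self, points: np.ndarray, clip: bool = False, return_converged: bool = False
    ):
        pts = np.atleast_2d(np.asarray(points, float))
        x = pts.copy()
        converged = np.zeros(len(pts), dtype=bool)
        for _ in range(self.max_iter):
            active = ~converged
            if not np.any(active):
                break
            d = self.forward.displacement_at(x[active], clip=True)
            x_new = pts[active] - d
            step = np.max(np.abs(x_new - x[active]), axis=1)
            x[active] = x_new
            done = step < self.tol
            idx = np.flatnonzero(active)
            converged[idx[done]] = True
        self.last_unconverged_fraction = float(np.mean(~converged)) if len(pts) else 0.0
        out = x - pts
        if np.asarray(points).ndim == 1:
            out = out[0]
        if return_converged:
            return out, converged
        return out

    def inverse(self):
        return self.forward


def _inverse_of(t):
    if hasattr(t, "inverse"):
        return t.inverse()
    return NumericalInverse(t)


# ---------------------------------------------------------------------------
# Synthesis


def identity_transform(frame: FrameGeometry, control_spacing: float = 32.0) -> BSplineTransform:
    """All-zero coefficient grid covering ``frame`` with cubic margin."""
    origin, shape = _covering_grid(frame, control_spacing)
    coeff = np.zeros(shape + (3,))
    return BSplineTransform(origin, (control_spacing,) * 3, coeff)


def _covering_grid(frame: FrameGeometry, h: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    lo, hi = frame.center_bbox_mm
    origin = lo - 2.0 * h
    m = tuple(int(np.ceil((hi[a] - origin[a]) / h)) + 3 for a in range(3))
    return origin, m


def random_transform(
    frame: FrameGeometry,
    control_spacing: float = 32.0,
    max_coeff: float = 5.0,
    seed: int | None = None,
    smooth_sigma: float = 0.0,
) -> BSplineTransform:
    """Smooth random deformation with displacement vanishing at the volume faces.

    Coefficients are i.i.d. uniform in [-max_coeff, +max_coeff] per
    component; every control point within two control spacings of a volume
    face (or outside the volume) is zeroed, so the cubic support of the
    boundary is entirely zero and no material point crosses the frame.

    ``smooth_sigma`` (in control-grid units) optionally correlates the
    coefficients with a Gaussian filter before boundary zeroing, producing
    longer-wavelength fields.  Raw i.i.d. coefficients give short-
    wavelength fields whose displacement gradient reaches 1 (a folding,
    non-invertible map) once displacements approach roughly 0.4x the
    control spacing; coherent anatomical deformations of large magnitude
    are only reproducible with the smoothed variant.
    """
    if control_spacing <= 0:
        raise ValueError("control spacing must be positive")
    if control_spacing < 4.0 * max(frame.spacing[0], frame.spacing[1]):
        raise ValueError(
            "control spacing must be at least 4x the in-plane voxel spacing "
            f"(got {control_spacing} mm for spacing {frame.spacing})"
        )
    rng = np.random.default_rng(seed)
    origin, shape = _covering_grid(frame, control_spacing)
    coeff = rng.uniform(-max_coeff, max_coeff, size=shape + (3,))
    if smooth_sigma > 0:
        coeff = ndimage.gaussian_filter(coeff, sigma=(smooth_sigma,) * 3 + (0.0,))
    lo, hi = frame.center_bbox_mm
    for a in range(3):
        pos = origin[a] + np.arange(shape[a]) * control_spacing
        interior = (pos >= lo[a] + 2.0 * control_spacing) & (pos <= hi[a] - 2.0 * control_spacing)
        sel = [slice(None)] * 3
        sel[a] = ~interior
        coeff[tuple(sel)] = 0.0
    return BSplineTransform(origin, (control_spacing,) * 3, coeff)


def scale_transform(t: BSplineTransform, factor: float) -> BSplineTransform:
    """Multiply all coefficients by ``factor`` (displacement scales exactly
    linearly with it)."""
    if factor < 0:
        raise ValueError("scale factor must be nonnegative")
    return BSplineTransform(t.control_origin, t.control_spacing, t.coefficients * factor)


# ---------------------------------------------------------------------------
# Displacement error


def _de_from_residuals(eps: np.ndarray) -> tuple[float, float]:
    de = float(np.sqrt(np.mean(np.sum(eps**2, axis=1))))
    axial = float(np.sqrt(np.mean(np.sum(eps[:, :2] ** 2, axis=1))))
    return de, axial


def true_de(t, sample_points) -> tuple[float, float]:
    """Exact displacement error of a transform over a sampled point set.

    Returns ``(de_mm, axial_de_mm)``: the RMS of the 3D displacement
    magnitude and of its in-plane (x, y) component.
    """
    pts = sample_points.points if isinstance(sample_points, PointSet) else np.atleast_2d(sample_points)
    if len(pts) == 0:
        raise ValueError("empty point set")
    d = t.displacement_at(pts)
    return _de_from_residuals(d)


def true_de_dense(t, frame: FrameGeometry, x_chunk: int = 64) -> tuple[float, float]:
    """Displacement error over every voxel of ``frame`` (Eq.-level truth).

    Streams the separable dense evaluation in x-slabs so the full field is
    never materialized for large frames.
    """
    By = t._axis_basis(frame, 1)
    Bz = t._axis_basis(frame, 2)
    a1 = np.tensordot(Bz, t.coefficients, axes=(1, 2))  # (nz, mx, my, 3)
    a2 = np.tensordot(By, a1, axes=(1, 2))  # (ny, nz, mx, 3)
    Bx = t._axis_basis(frame, 0)
    n_total = 0
    ssq3 = 0.0
    ssq2 = 0.0
    for s in range(0, frame.shape[0], x_chunk):
        d = np.tensordot(Bx[s : s + x_chunk], a2, axes=(1, 2))  # (cx, ny, nz, 3)
        sq = d * d
        ssq3 += float(sq.sum())
        ssq2 += float(sq[..., :2].sum())
        n_total += d.shape[0] * d.shape[1] * d.shape[2]
    return float(np.sqrt(ssq3 / n_total)), float(np.sqrt(ssq2 / n_total))


def compose_residual(t0, t_rec, sample_points) -> tuple[float, float]:
    """DE of the residual map ``t_rec ∘ t0`` against identity.

    Each point x is pushed forward through the true deformation, then
    through the recovered one; a perfect recovery returns every point to
    its start and yields (0, 0).  Points whose forward image leaves the
    recovered transform's support are excluded; more than 10% exclusions is
    an error.
    """
    pts = sample_points.points if isinstance(sample_points, PointSet) else np.atleast_2d(sample_points)
    if len(pts) == 0:
        raise ValueError("empty point set")
    y = pts + t0.displacement_at(pts)
    keep = np.ones(len(pts), dtype=bool)
    if hasattr(t_rec, "support_lo"):
        keep = np.all((y >= t_rec.support_lo) & (y <= t_rec.support_hi), axis=1)
    if np.mean(~keep) > 0.10:
        raise ValueError(
            f"{int((~keep).sum())} of {len(pts)} points leave the recovered transform's support"
        )
    z = y[keep] + t_rec.displacement_at(y[keep])
    return _de_from_residuals(z - pts[keep])


# ---------------------------------------------------------------------------
# Warping


def warp_volume(
    v: Volume,
    t,
    pad: float = 0.0,
    tol: float = 0.01,
    max_iter: int = 20,
    max_unconverged: float = 0.001,
) -> Volume:
    """Warp a dense volume by a forward transform.

    Backward resampling: each output voxel center y is traced to the source
    position x solving ``x + d(x) = y`` (fixed-point inversion, ``tol`` mm,
    at most ``max_iter`` sweeps per voxel) and trilinearly interpolated.
    Positions outside the field of view receive ``pad``.
    """
    frame = v.geometry
    centers = frame.voxel_centers().reshape(-1, 3)
    inv = _inverse_of(t)
    if isinstance(inv, NumericalInverse):
        inv = NumericalInverse(inv.forward, tol=tol, max_iter=max_iter)
        disp, converged = inv.displacement_at(centers, return_converged=True)
        frac_bad = float(np.mean(~converged))
        if frac_bad > max_unconverged:
            raise ConvergenceError(
                f"forward-map inversion failed at {frac_bad:.2%} of voxels; "
                "the deformation is too strong for fixed-point inversion — use a smaller one"
            )
    else:
        disp = inv.displacement_at(centers)
    # index-space source coordinates; exactly integral for the identity so
    # the resample is bit-exact in that case
    idx = np.indices(frame.shape).reshape(3, -1).T.astype(float)
    coords = idx + disp / np.asarray(frame.spacing)
    # the field of view extends half a voxel beyond the outer centers:
    # edge-extend inside that border, pad only genuinely out-of-field voxels
    shape_arr = np.asarray(frame.shape, float)
    out_of_field = np.any((coords < -0.5) | (coords > shape_arr - 0.5), axis=1)
    coords = np.clip(coords, 0.0, shape_arr - 1.0)
    out = ndimage.map_coordinates(
        np.asarray(v.data, float), coords.T, order=1, mode="nearest"
    )
    out[out_of_field] = pad
    return Volume(out.reshape(frame.shape), v.spacing, v.origin, modality=v.modality, meta=dict(v.meta))
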