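"""Digital multimodality phantom: cylindrical water tank with plastic spheres.

Emulates a registration-QA phantom: a water-filled cylinder with a plastic
base slab (carrying a 12x12 grid of threaded mounting holes, 8 mm pitch)
and solid plastic spheres distributed through the water.  Paired
"scenarios" perturb one sphere — an 8 mm translation or a replacement that
changes its radius — and render source/target image pairs in CT, MRI and
PET so that a registration system's response to a purely local change can
be studied with the true displacement known.

Rendering is geometric, not physical: per-voxel material occupancy
(8x supersampled on boundary-containing voxels), a material-to-intensity
map per modality, an isotropic Gaussian point-spread blur at the system
resolution, and additive Gaussian noise.  MRI assigns no signal to
plastic, which reproduces the apparent shrinkage of the phantom perimeter
relative to CT when the cylinder has a plastic wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import FrameGeometry, Volume

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Sphere:
    id: str
    center: tuple[float, float, float]  # mm, in phantom coordinates (z=0 at cylinder base)
    radius: float


@dataclass(frozen=True)
class Translate:
    sphere_id: str
    vector: tuple[float, float, float]


@dataclass(frozen=True)
class Resize:
    sphere_id: str
    new_radius: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the physical phantom, in mm.

    The hole grid is carried as mounting metadata (it fixes the 8 mm
    translation pitch); holes and rods are not rendered.
    """

    cylinder_radius: float = 100.0
    cylinder_height: float = 120.0
    wall_thickness: float = 3.0
    base_slab_thickness: float = 10.0
    hole_grid: tuple[int, int, float] = (12, 12, 8.0)  # nx, ny, pitch mm
    spheres: tuple[Sphere, ...] = ()
    seed: int = 0

    def __post_init__(self):
        errors = []
        if self.hole_grid[2] <= 0:
            errors.append("hole grid pitch must be positive")
        if self.cylinder_radius <= self.wall_thickness:
            errors.append("cylinder radius must exceed wall thickness")
        inner = self.cylinder_radius - self.wall_thickness
        for s in self.spheres:
            cx, cy, cz = s.center
            r_xy = float(np.hypot(cx, cy))
            if r_xy + s.radius > inner:
                errors.append(f"sphere {s.id} pokes through the cylinder wall")
            if cz - s.radius < self.base_slab_thickness:
                errors.append(f"sphere {s.id} intersects the base slab")
            if cz + s.radius > self.cylinder_height:
                errors.append(f"sphere {s.id} pokes out of the top")
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1 :]:
                gap = float(np.linalg.norm(np.subtract(a.center, b.center)))
                if gap < a.radius + b.radius:
                    errors.append(f"spheres {a.id} and {b.id} intersect")
        if errors:
            raise ValueError("invalid phantom spec: " + "; ".join(errors))

    def sphere(self, sphere_id: str) -> Sphere:
        for s in self.spheres:
            if s.id == sphere_id:
                return s
        raise KeyError(f"no sphere with id {sphere_id!r}")


def default_spec(seed: int = 0) -> PhantomSpec:
    """Seven spheres, radii 5-15 mm, fairly evenly spread through the water."""
    centers = [
        (-55.0, -35.0, 40.0),
        (55.0, -40.0, 35.0),
        (0.0, 60.0, 45.0),
        (-45.0, 45.0, 80.0),
        (50.0, 40.0, 85.0),
        (0.0, -60.0, 85.0),
        (0.0, 0.0, 60.0),
    ]
    radii = [15.0, 12.5, 11.0, 10.0, 8.0, 6.5, 5.0]
    spheres = tuple(
        Sphere(id=f"S{i + 1}", center=c, radius=r) for i, (c, r) in enumerate(zip(centers, radii))
    )
    return PhantomSpec(spheres=spheres, seed=seed)


@dataclass(frozen=True)
class ModalityModel:
    """Acquisition model: grid geometry, intensity map, resolution, noise."""

    modality: str
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    intensities: dict = field(default_factory=dict)  # water/plastic/air -> scalar
    psf_fwhm_mm: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.psf_fwhm_mm < 0 or self.noise_sigma < 0:
            raise ValueError("psf_fwhm and noise_sigma must be nonnegative")
        for mat in ("water", "plastic", "air"):
            if mat not in self.intensities:
                raise ValueError(f"intensity map must define {mat!r}")

    def frame(self) -> FrameGeometry:
        # center the phantom: origin places the volume symmetric about x=y=0
        # with z spanning the cylinder from slightly below the base
        ext = np.asarray(self.shape) * np.asarray(self.spacing)
        origin = (
            -ext[0] / 2 + self.spacing[0] / 2,
            -ext[1] / 2 + self.spacing[1] / 2,
            -10.0 + self.spacing[2] / 2,
        )
        return FrameGeometry(self.shape, self.spacing, origin)


def ct_model() -> ModalityModel:
    return ModalityModel(
        modality="CT",
        shape=(512, 512, 62),
        spacing=(0.9, 0.9, 2.0),
        intensities={"water": 0.0, "plastic": 120.0, "air": -1000.0},
        psf_fwhm_mm=0.7,
        noise_sigma=10.0,
    )


def mri_model() -> ModalityModel:
    # T1 water signal; plastic and air are signal voids
    return ModalityModel(
        modality="MRI",
        shape=(512, 512, 21),
        spacing=(0.6, 0.6, 5.0),
        intensities={"water": 1000.0, "plastic": 0.0, "air": 0.0},
        psf_fwhm_mm=0.8,
        noise_sigma=20.0,
    )


def pet_model() -> ModalityModel:
    # FDG solution in the water; plastic displaces activity
    return ModalityModel(
        modality="PET",
        shape=(144, 144, 30),
        spacing=(4.0, 4.0, 4.0),
        intensities={"water": 1.0, "plastic": 0.0, "air": 0.0},
        psf_fwhm_mm=6.5,
        noise_sigma=0.02,
    )


def _slice_intensity(
    xs: np.ndarray, ys: np.ndarray, z: float, spec: PhantomSpec, model: ModalityModel
) -> np.ndarray:
    """Intensity on one axial sample plane (xs, ys are 1-D mm axes)."""
    i_w = model.intensities["water"]
    i_p = model.intensities["plastic"]
    i_a = model.intensities["air"]
    r2 = xs[:, None] ** 2 + ys[None, :] ** 2
    R = spec.cylinder_radius
    out = np.full(r2.shape, i_a, float)
    if not (0.0 <= z <= spec.cylinder_height):
        return out
    inside_cyl = r2 <= R**2
    plastic = inside_cyl & ((r2 > (R - spec.wall_thickness) ** 2) | (z <= spec.base_slab_thickness))
    water = inside_cyl & ~plastic
    out[plastic] = i_p
    out[water] = i_w
    for s in spec.spheres:
        dz2 = (z - s.center[2]) ** 2
        if dz2 > s.radius**2:
            continue
        rxy2 = s.radius**2 - dz2
        rxy = np.sqrt(rxy2)
        wx = (xs >= s.center[0] - rxy) & (xs <= s.center[0] + rxy)
        wy = (ys >= s.center[1] - rxy) & (ys <= s.center[1] + rxy)
        if not (wx.any() and wy.any()):
            continue
        ix = np.ix_(wx, wy)
        d2 = (xs[wx, None] - s.center[0]) ** 2 + (ys[None, wy] - s.center[1]) ** 2
        inside = water[ix] & (d2 <= rxy2)
        sub = out[ix]
        sub[inside] = i_p
        out[ix] = sub
    return out


def render(spec: PhantomSpec, model: ModalityModel, supersample: int = 2) -> Volume:
    """Render the phantom on the modality's grid.

    Each voxel intensity is the mean over ``supersample``^3 subsamples
    (partial-volume rendering), then blurred with a Gaussian PSF at the
    modality's FWHM and degraded with additive Gaussian noise seeded from
    the spec, so the noise-free render is seed-independent.
    """
    frame = model.frame()
    sp = np.asarray(frame.spacing)
    xs = frame.origin[0] + np.arange(frame.shape[0]) * sp[0]
    ys = frame.origin[1] + np.arange(frame.shape[1]) * sp[1]
    zs = frame.origin[2] + np.arange(frame.shape[2]) * sp[2]
    offsets = (np.arange(supersample) + 0.5) / supersample - 0.5  # in voxel units
    acc = np.zeros(frame.shape)
    for ox in offsets:
        X = xs + ox * sp[0]
        for oy in offsets:
            Y = ys + oy * sp[1]
            for oz in offsets:
                for k, z in enumerate(zs + oz * sp[2]):
                    acc[:, :, k] += _slice_intensity(X, Y, float(z), spec, model)
    acc /= supersample**3
    if model.psf_fwhm_mm > 0:
        sigma_vox = model.psf_fwhm_mm * _FWHM_TO_SIGMA / sp
        acc = ndimage.gaussian_filter(acc, sigma=sigma_vox)
    if model.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        acc = acc + rng.normal(0.0, model.noise_sigma, size=acc.shape)
    return Volume(acc, frame.spacing, frame.origin, modality=model.modality)


def modify(spec: PhantomSpec, change: Translate | Resize) -> PhantomSpec:
    """New spec differing only in the named sphere; invariant violations raise."""
    old = spec.sphere(change.sphere_id)
    if isinstance(change, Translate):
        new = Sphere(old.id, tuple(np.add(old.center, change.vector)), old.radius)
    elif isinstance(change, Resize):
        if change.new_radius <= 0:
            raise ValueError("sphere radius must be positive")
        new = Sphere(old.id, old.center, float(change.new_radius))
    else:
        raise TypeError(f"unknown change {change!r}")
    spheres = tuple(new if s.id == old.id else s for s in spec.spheres)
    return replace(spec, spheres=spheres)  # __post_init__ re-validates


@dataclass
class Scenario:
    """A paired phantom modification with its ground truth.

    ``pairs`` holds (source, target, modality) triples: the target is the
    reference setup, the source the modified one, as acquired by each
    modality.  ``truth`` records the modified sphere and its displacement
    so downstream registration evaluations have an absolute reference.
    """

    pairs: list[tuple[Volume, Volume, str]]
    truth: dict


def scenario_pair(spec: PhantomSpec, change: Translate | Resize, models) -> Scenario:
    modified = modify(spec, change)
    pairs = []
    for model in models:
        target = render(spec, model)
        source = render(modified, model)
        pairs.append((source, target, model.modality))
    if isinstance(change, Translate):
        vec = tuple(float(v) for v in change.vector)
        truth = {
            "sphere_id": change.sphere_id,
            "change": "translate",
            "displacement_mm": vec,
            "displacement_magnitude_mm": float(np.linalg.norm(vec)),
        }
    else:
        old = spec.sphere(change.sphere_id)
        truth = {
            "sphere_id": change.sphere_id,
            "change": "resize",
            "old_radius_mm": old.radius,
            "new_radius_mm": float(change.new_radius),
            "volume_ratio": float((change.new_radius / old.radius) ** 3),
        }
    return Scenario(pairs=pairs, truth=truth)


def apparent_radius(v: Volume, n_rays: int = 8) -> float:
    """Half-maximum apparent cylinder radius on a mid-water axial slice.

    Walks radial profiles outward from the cylinder axis and finds where
    intensity first crosses halfway between the central (water) level and
    the outside (air/background) level, averaged over ``n_rays`` rays.
    Sub-sample positions come from linear interpolation across the
    crossing.
    """
    frame = v.geometry
    # slice at mid-height of the water column, above the slab
    k = int(round((60.0 - frame.origin[2]) / frame.spacing[2]))
    k = int(np.clip(k, 0, frame.shape[2] - 1))
    sl = np.asarray(v.data[:, :, k], float)
    xs = frame.origin[0] + np.arange(frame.shape[0]) * frame.spacing[0]
    ys = frame.origin[1] + np.arange(frame.shape[1]) * frame.spacing[1]
    r_grid = np.hypot(xs[:, None], ys[None, :])
    # medians make both levels robust to spheres (signal voids) and noise
    water_level = float(np.median(sl[r_grid < 40.0]))
    air_level = float(np.median(sl[r_grid > 0.95 * r_grid.max()]))
    half = 0.5 * (water_level + air_level)
    falling = water_level > air_level
    radii = []
    step = min(frame.spacing[0], frame.spacing[1]) / 2.0
    max_r = min(frame.extent_mm[0], frame.extent_mm[1]) / 2.0 - step
    rs = np.arange(0.0, max_r, step)
    for theta in np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False):
        px = rs * np.cos(theta)
        py = rs * np.sin(theta)
        ix = (px - frame.origin[0]) / frame.spacing[0]
        iy = (py - frame.origin[1]) / frame.spacing[1]
        prof = ndimage.map_coordinates(sl, [ix, iy], order=1, mode="nearest")
        beyond = prof < half if falling else prof > half
        cross = np.flatnonzero(beyond[1:] & ~beyond[:-1])
        if len(cross) == 0:
            continue
        # outermost crossing: a sphere (signal void) on the ray dips the
        # profile too, but the phantom boundary is the last transition
        i = int(cross[-1])
        f = (half - prof[i]) / (prof[i + 1] - prof[i])
        radii.append(rs[i] + f * step)
    if not radii:
        raise ValueError("no half-maximum crossing found; is this a phantom image?")
    return float(np.mean(radii))
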