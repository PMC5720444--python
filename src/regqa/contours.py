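"""Binary-mask overlap and surface-distance metrics for inter-modality validation.

Given two regions of interest delineated on registered images (e.g. a
prostate contoured on CT and on deformably registered MRI), agreement is
quantified by:

* Tannimoto coefficient  TC  = |A ∩ B| / |A ∪ B|  (intersection over union),
* Dice similarity coefficient  DSC = 2|A ∩ B| / (|A| + |B|),
* mean surface distance: the symmetric average of nearest-surface-voxel
  distances (mm) between the two mask boundaries.

TC and DSC both range from 0 (no overlap) to 1 (identical volumes) and are
algebraically linked by DSC = 2·TC / (1 + TC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import BinaryMask, GeometryMismatchError, Volume


@dataclass
class ContourMetrics:
    tc: float
    dsc: float
    mean_surface_distance_mm: float
    vol_a_mm3: float
    vol_b_mm3: float


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if (
        a.data.shape != b.data.shape
        or not np.allclose(a.spacing, b.spacing, atol=1e-6)
        or not np.allclose(a.origin, b.origin, atol=1e-6)
    ):
        raise GeometryMismatchError("mask pair must share shape, spacing and origin")


def tannimoto(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union by voxel counting; undefined for two empty masks."""
    _check_pair(a, b)
    inter = int(np.count_nonzero(a.data & b.data))
    union = int(np.count_nonzero(a.data | b.data))
    if union == 0:
        raise ValueError("Tannimoto coefficient undefined for two empty masks")
    return inter / union


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """2|A∩B| / (|A|+|B|); undefined for two empty masks."""
    _check_pair(a, b)
    inter = int(np.count_nonzero(a.data & b.data))
    total = int(np.count_nonzero(a.data)) + int(np.count_nonzero(b.data))
    if total == 0:
        raise ValueError("Dice coefficient undefined for two empty masks")
    return 2.0 * inter / total


def surface_voxels(m: BinaryMask) -> np.ndarray:
    """Boolean array of mask voxels with at least one false 6-neighbor.

    Voxels on the volume faces count their out-of-volume neighbors as
    false, so a mask touching the border still has a surface there.
    """
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(m.data, structure=structure, border_value=0)
    return m.data & ~eroded


def mean_surface_distance(a: BinaryMask, b: BinaryMask) -> float:
    """Symmetric mean nearest-neighbor distance (mm) between mask surfaces.

    Surfaces are voxel sets (6-connectivity complement test); distances are
    Euclidean between voxel centers in physical mm, so anisotropic spacings
    are honored.  The two directed means are averaged.
    """
    _check_pair(a, b)
    if not a.data.any() or not b.data.any():
        raise ValueError("mean surface distance undefined for an empty mask")
    spacing = np.asarray(a.spacing)
    origin = np.asarray(a.origin)
    pa = np.argwhere(surface_voxels(a)) * spacing + origin
    pb = np.argwhere(surface_voxels(b)) * spacing + origin
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return 0.5 * (float(np.mean(d_ab)) + float(np.mean(d_ba)))


def binary_from_volume(v: Volume, threshold: float = 0.5) -> BinaryMask:
    """Re-binarize an (interpolated) 0/1 image: mask = intensity >= threshold.

    The 0.5 default recovers a mask after a binary image has passed through
    a trilinear resampler.
    """
    return BinaryMask(np.asarray(v.data, float) >= threshold, v.spacing, v.origin)


def contour_metrics(a: BinaryMask, b: BinaryMask) -> ContourMetrics:
    """TC, DSC, mean surface distance and both volumes for a mask pair."""
    return ContourMetrics(
        tc=tannimoto(a, b),
        dsc=dice(a, b),
        mean_surface_distance_mm=mean_surface_distance(a, b),
        vol_a_mm3=a.volume_mm3,
        vol_b_mm3=b.volume_mm3,
    )
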