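"""Per-target SUV statistics, volume, and the trial's inclusion filters.

Three standard uptake statistics are computed per contoured target:

* ``SUV_max`` — maximum SUV inside the contour;
* ``SUV_mean`` — arithmetic mean over the contour;
* ``SUV_peak`` — mean within a ~1.2-cm-diameter (1 mL) sphere centered at
  the contour's hottest voxel; the sphere may extend beyond the contour.

Two trial filters gate targets into the statistical analysis:

* evaluability: contour volume >= 1.728 mL (a 3x3x3-voxel block at 4-mm
  isotropic spacing), boundary inclusive — only targets *smaller* than the
  block are excluded;
* FDG avidity: baseline SUV_max >= 7.5 g/mL marks the high-metabolism,
  highest-risk subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import GridSpec, SuvImage

__all__ = [
    "EVALUABLE_VOLUME_ML",
    "FDG_AVID_SUV_MAX",
    "LesionMetrics",
    "suv_from_activity",
    "suv_max",
    "suv_mean",
    "suv_peak",
    "volume_ml",
    "is_evaluable",
    "is_fdg_avid",
    "compute_lesion_metrics",
    "sphere_volume_ml",
    "sphere_diameter_cm",
]

#: Minimum evaluable target volume: 3 x 3 x 3 voxels at 4-mm spacing.
EVALUABLE_VOLUME_ML = 1.728
#: Baseline SUV_max at or above which a target counts as FDG-avid (g/mL).
FDG_AVID_SUV_MAX = 7.5
#: SUV_peak sphere volume (mL); diameter ~1.2 cm.
PEAK_SPHERE_VOLUME_ML = 1.0


def sphere_volume_ml(diameter_mm: float) -> float:
    """Volume (mL) of a sphere of the given diameter in mm."""
    r = diameter_mm / 2.0
    return 4.0 / 3.0 * math.pi * r**3 / 1000.0


def sphere_diameter_cm(volume_ml: float) -> float:
    """Diameter (cm) of a sphere of the given volume in mL."""
    r_mm = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return 2.0 * r_mm / 10.0


@dataclass
class LesionMetrics:
    """SUV statistics and filter flags for one target at one timepoint."""

    lesion_id: int
    suv_max: float
    suv_mean: float
    suv_peak: float | None  # absent for targets too small to host the sphere
    volume_ml: float
    evaluable: bool
    fdg_avid: bool


def suv_from_activity(conc_kbq_ml: np.ndarray, dose_mbq: float, mass_kg: float) -> np.ndarray:
    """Convert activity concentration to body-mass-normalised SUV.

    ``SUV = concentration [kBq/mL] / (injected dose [kBq] / body mass [g])``,
    dimensionally g/mL.
    """
    if dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if mass_kg <= 0:
        raise ValueError("body mass must be positive")
    conc = np.asarray(conc_kbq_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be non-negative")
    dose_kbq = dose_mbq * 1000.0
    mass_g = mass_kg * 1000.0
    return conc / (dose_kbq / mass_g)


def _masked_values(image: SuvImage, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.values.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("mask is empty")
    return image.values[mask]


def suv_max(image: SuvImage, mask: np.ndarray) -> float:
    """Maximum SUV within the contour."""
    return float(_masked_values(image, mask).max())


def suv_mean(image: SuvImage, mask: np.ndarray) -> float:
    """Arithmetic mean SUV within the contour."""
    return float(_masked_values(image, mask).mean())


def _sphere_offsets(grid: GridSpec, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centers lie within radius_mm of a voxel center."""
    reach = np.floor(radius_mm / grid.spacing).astype(int)
    oi, oj, ok = [np.arange(-n, n + 1) for n in reach]
    di, dj, dk = np.meshgrid(oi, oj, ok, indexing="ij")
    d2 = (
        (di * grid.spacing[0]) ** 2
        + (dj * grid.spacing[1]) ** 2
        + (dk * grid.spacing[2]) ** 2
    )
    inside = d2 <= radius_mm**2
    return np.stack([di[inside], dj[inside], dk[inside]], axis=1)


def _sphere_mean_at(image: SuvImage, center_idx: np.ndarray, offsets: np.ndarray) -> float:
    idx = offsets + center_idx
    shape = np.asarray(image.grid.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)  # clip to image bounds
    idx = idx[ok]
    return float(image.values[idx[:, 0], idx[:, 1], idx[:, 2]].mean())


def suv_peak(
    image: SuvImage,
    mask: np.ndarray,
    sphere_volume_ml: float = PEAK_SPHERE_VOLUME_ML,
    maximize_sphere_mean: bool = False,
) -> float | None:
    """Mean SUV within a sphere at the target's most active part.

    The sphere radius follows from the requested volume
    (``r = (3V / 4 pi)^(1/3)``, ~6.2 mm for 1 mL).  By default the sphere
    is centered at the hottest masked voxel; exact ties (e.g. a perfectly
    uniform synthetic lesion) break toward the voxel nearest the mask
    centroid, then the lowest linear index, so a flat plateau peaks at its
    middle rather than a corner.  With ``maximize_sphere_mean=True`` it is
    instead placed
    at the masked voxel that maximizes the sphere mean, the placement used
    by some PERCIST implementations.  The sphere may extend beyond the
    contour and is clipped to the image bounds.

    Returns ``None`` when the grid spacing is too coarse for the sphere to
    span at least two voxels, mirroring targets whose SUV_peak cannot be
    computed.
    """
    mask = np.asarray(mask, dtype=bool)
    _masked_values(image, mask)  # validates
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    offsets = _sphere_offsets(image.grid, radius_mm)
    if offsets.shape[0] < 2:
        return None

    mask_lin = np.flatnonzero(mask.ravel())
    if maximize_sphere_mean:
        best_val = -np.inf
        best = None
        for lin in mask_lin:
            cidx = np.asarray(np.unravel_index(lin, mask.shape))
            val = _sphere_mean_at(image, cidx, offsets)
            if val > best_val:
                best_val = val
                best = cidx
        return _sphere_mean_at(image, best, offsets)

    vals = image.values.ravel()[mask_lin]
    tied = mask_lin[vals == vals.max()]
    if tied.size > 1:
        cand = np.stack(np.unravel_index(tied, mask.shape), axis=1).astype(float)
        centroid = np.stack(np.nonzero(mask), axis=1).mean(axis=0)
        d2 = (((cand - centroid) * image.grid.spacing) ** 2).sum(axis=1)
        # lowest linear index among equidistant candidates (tied is sorted)
        hottest = cand[int(np.argmin(d2))].astype(int)
    else:
        hottest = np.asarray(np.unravel_index(tied[0], mask.shape))
    return _sphere_mean_at(image, hottest, offsets)


def volume_ml(mask: np.ndarray, grid: GridSpec) -> float:
    """Contour volume: voxel count times voxel volume, in mL."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask is empty")
    return n * grid.voxel_volume_ml


def is_evaluable(volume: float, threshold_ml: float = EVALUABLE_VOLUME_ML) -> bool:
    """True iff the target is at least 1.728 mL (inclusive boundary)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return volume >= threshold_ml


def is_fdg_avid(suv_max_value: float, threshold: float = FDG_AVID_SUV_MAX) -> bool:
    """True iff baseline SUV_max is 7.5 g/mL or higher."""
    if suv_max_value < 0:
        raise ValueError("suv_max must be non-negative")
    return suv_max_value >= threshold


def compute_lesion_metrics(
    image: SuvImage,
    mask: np.ndarray,
    lesion_id: int = 0,
    maximize_sphere_mean: bool = False,
) -> LesionMetrics:
    """All per-target statistics and filter flags in one pass."""
    vol = volume_ml(mask, image.grid)
    smax = suv_max(image, mask)
    return LesionMetrics(
        lesion_id=lesion_id,
        suv_max=smax,
        suv_mean=suv_mean(image, mask),
        suv_peak=suv_peak(image, mask, maximize_sphere_mean=maximize_sphere_mean),
        volume_ml=vol,
        evaluable=is_evaluable(vol),
        fdg_avid=is_fdg_avid(smax),
    )
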