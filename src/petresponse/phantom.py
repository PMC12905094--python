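"""Synthetic FDG-PET phantom generation with known lesion truth.

Generates paired pre/post torso-style SUV volumes containing ellipsoidal
focal lesions of known true SUV over a low uniform background, degraded by
Gaussian scanner blur and additive noise.  Every downstream stage of the
pipeline (delineation, quantification, partial-volume correction, response
classification) can therefore be validated against exact ground truth.

Simulation chain per timepoint: rasterize -> scanner blur -> noise.  The
follow-up study reuses the baseline geometry and scales each lesion's true
SUV by its prescribed relative difference, i.e. a purely metabolic (not
volumetric) change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import GridSpec, SuvImage

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PairedStudySpec",
    "GroundTruthManifest",
    "rasterize_lesions",
    "apply_scanner_blur",
    "add_noise",
    "generate_paired_study",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal focal lesion (a sphere when all semi-axes are equal)."""

    lesion_id: int
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    true_suv: float

    def __post_init__(self):
        axes = tuple(float(a) for a in self.semi_axes_mm)
        if len(axes) != 3 or any(a <= 0 for a in axes):
            raise ValueError("semi_axes_mm must be three positive scalars")
        object.__setattr__(self, "semi_axes_mm", axes)
        object.__setattr__(self, "center_mm", tuple(float(c) for c in self.center_mm))
        if self.true_suv <= 0:
            raise ValueError("true_suv must be positive")

    @property
    def true_volume_ml(self) -> float:
        """Analytic ellipsoid volume in mL."""
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    @property
    def longest_axis(self) -> int:
        return int(np.argmax(self.semi_axes_mm))


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic SUV study."""

    grid: GridSpec
    background_suv: float
    lesions: tuple[LesionSpec, ...]
    blur_fwhm_mm: float = 4.0
    noise_sigma_suv: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if self.background_suv < 0:
            raise ValueError("background_suv must be non-negative")
        if self.blur_fwhm_mm < 0:
            raise ValueError("blur_fwhm_mm must be non-negative")
        if self.noise_sigma_suv < 0:
            raise ValueError("noise_sigma_suv must be non-negative")
        ids = [les.lesion_id for les in self.lesions]
        if len(set(ids)) != len(ids):
            raise ValueError("lesion ids must be unique")
        if self.lesions and any(n < 8 for n in self.grid.shape):
            raise ValueError("grid must be at least 8 voxels per axis to carry a lesion")
        for les in self.lesions:
            if les.true_suv <= self.background_suv:
                raise ValueError(
                    f"lesion {les.lesion_id}: true_suv must exceed the background"
                )
            contrast = les.true_suv - self.background_suv
            if self.noise_sigma_suv >= contrast:
                raise ValueError(
                    f"lesion {les.lesion_id}: noise sigma must stay below the "
                    "lesion-background contrast so truth remains recoverable"
                )

    def with_scaled_lesions(self, scale: dict[int, float]) -> "PhantomSpec":
        """Copy with each lesion's true SUV multiplied by ``scale[lesion_id]``."""
        lesions = []
        for les in self.lesions:
            s = scale.get(les.lesion_id, 1.0)
            lesions.append(
                LesionSpec(
                    lesion_id=les.lesion_id,
                    center_mm=les.center_mm,
                    semi_axes_mm=les.semi_axes_mm,
                    true_suv=les.true_suv * s,
                )
            )
        return PhantomSpec(
            grid=self.grid,
            background_suv=self.background_suv,
            lesions=tuple(lesions),
            blur_fwhm_mm=self.blur_fwhm_mm,
            noise_sigma_suv=self.noise_sigma_suv,
            rng_seed=self.rng_seed,
        )


@dataclass(frozen=True)
class PairedStudySpec:
    """Baseline phantom plus per-lesion true relative differences (%).

    The follow-up true SUV of lesion *i* is
    ``baseline true_suv * (1 + true_rd_percent[i] / 100)``; lesion geometry
    is identical pre/post, so only metabolic change is simulated.
    """

    baseline: PhantomSpec
    true_rd_percent: dict[int, float]

    def __post_init__(self):
        known = {les.lesion_id for les in self.baseline.lesions}
        for lid, rd in self.true_rd_percent.items():
            if lid not in known:
                raise ValueError(f"true_rd_percent refers to unknown lesion id {lid}")
            if 1.0 + rd / 100.0 < 0:
                raise ValueError(f"lesion {lid}: follow-up true SUV would be negative")


@dataclass
class LesionTruth:
    lesion_id: int
    true_suv_pre: float
    true_suv_post: float
    true_rd_percent: float
    true_volume_ml: float
    center_voxel: tuple[int, int, int]
    semi_axes_mm: tuple[float, float, float]


@dataclass
class GroundTruthManifest:
    """Per-lesion truth of a paired synthetic study."""

    lesions: list[LesionTruth] = field(default_factory=list)

    def __post_init__(self):
        for t in self.lesions:
            if t.true_suv_pre > 0:
                rd = 100.0 * (t.true_suv_post - t.true_suv_pre) / t.true_suv_pre
                if abs(rd - t.true_rd_percent) > 1e-9 * max(1.0, abs(rd)):
                    raise ValueError(
                        f"lesion {t.lesion_id}: stored true_rd_percent inconsistent "
                        "with pre/post true SUVs"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.lesions:
            rows.append(
                {
                    "lesion_id": t.lesion_id,
                    "center_i": t.center_voxel[0],
                    "center_j": t.center_voxel[1],
                    "center_k": t.center_voxel[2],
                    "true_suv_pre": t.true_suv_pre,
                    "true_suv_post": t.true_suv_post,
                    "true_rd_percent": t.true_rd_percent,
                    "true_volume_ml": t.true_volume_ml,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "lesions": [
                {
                    "lesion_id": t.lesion_id,
                    "true_suv_pre": t.true_suv_pre,
                    "true_suv_post": t.true_suv_post,
                    "true_rd_percent": t.true_rd_percent,
                    "true_volume_ml": t.true_volume_ml,
                    "center_voxel": list(t.center_voxel),
                    "semi_axes_mm": list(t.semi_axes_mm),
                }
                for t in self.lesions
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        lesions = [
            LesionTruth(
                lesion_id=d["lesion_id"],
                true_suv_pre=d["true_suv_pre"],
                true_suv_post=d["true_suv_post"],
                true_rd_percent=d["true_rd_percent"],
                true_volume_ml=d["true_volume_ml"],
                center_voxel=tuple(d["center_voxel"]),
                semi_axes_mm=tuple(d["semi_axes_mm"]),
            )
            for d in payload["lesions"]
        ]
        return cls(lesions=lesions)


def _check_lesion_in_bounds(les: LesionSpec, grid: GridSpec) -> None:
    low, high = grid.bounds_mm
    center = np.asarray(les.center_mm)
    axes = np.asarray(les.semi_axes_mm)
    if np.any(center - axes < low) or np.any(center + axes > high):
        raise ValueError(
            f"lesion {les.lesion_id} extends outside the grid bounds "
            f"({center - axes} .. {center + axes} vs {low} .. {high})"
        )


def rasterize_lesions(spec: PhantomSpec) -> SuvImage:
    """Noise-free, blur-free rasterization of a phantom.

    A voxel takes the true SUV of the lesion whose ellipsoid contains its
    center (no partial-voxel weighting), otherwise the background.  Where
    lesions overlap the maximum SUV wins, which is order-independent.
    """
    grid = spec.grid
    for les in spec.lesions:
        _check_lesion_in_bounds(les, grid)
    values = np.full(grid.shape, float(spec.background_suv))
    if not spec.lesions:
        return SuvImage(values=values, grid=grid)

    cx = grid.voxel_centers_mm(0)
    cy = grid.voxel_centers_mm(1)
    cz = grid.voxel_centers_mm(2)
    for les in spec.lesions:
        c = np.asarray(les.center_mm)
        a = np.asarray(les.semi_axes_mm)
        # Work inside the lesion's bounding box only.
        sl = []
        for ax, (centers, ci, ai) in enumerate(zip((cx, cy, cz), c, a)):
            idx = np.nonzero(np.abs(centers - ci) <= ai)[0]
            if idx.size == 0:
                sl = None
                break
            sl.append(slice(idx[0], idx[-1] + 1))
        if sl is None:
            continue
        u = (cx[sl[0]] - c[0]) / a[0]
        v = (cy[sl[1]] - c[1]) / a[1]
        w = (cz[sl[2]] - c[2]) / a[2]
        inside = (
            u[:, None, None] ** 2 + v[None, :, None] ** 2 + w[None, None, :] ** 2
        ) <= 1.0
        box = values[tuple(sl)]
        box[inside] = np.maximum(box[inside], les.true_suv)
    return SuvImage(values=values, grid=grid)


def apply_scanner_blur(image: SuvImage, fwhm_mm: float) -> SuvImage:
    """Gaussian scanner blur with replicate boundary padding.

    Models the PET system's finite spatial resolution, the source of the
    partial volume effect.  ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis,
    expressed in voxels for the filter.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return image.with_values(image.values.copy())
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = sigma_mm / image.grid.spacing
    blurred = ndimage.gaussian_filter(image.values, sigma=sigma_vox, mode="nearest")
    return image.with_values(np.clip(blurred, 0.0, None))


def add_noise(image: SuvImage, sigma: float, seed: int) -> SuvImage:
    """Additive zero-mean Gaussian noise in SUV units, clipped at zero."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return image.with_values(image.values.copy())
    rng = np.random.default_rng(seed)
    noisy = image.values + rng.normal(0.0, sigma, size=image.values.shape)
    return image.with_values(np.clip(noisy, 0.0, None))


def simulate_phantom(spec: PhantomSpec, seed: int | None = None) -> SuvImage:
    """Full single-study simulation: rasterize -> blur -> noise."""
    if seed is None:
        seed = spec.rng_seed
    img = rasterize_lesions(spec)
    img = apply_scanner_blur(img, spec.blur_fwhm_mm)
    img = add_noise(img, spec.noise_sigma_suv, seed)
    return img


def _derive_seeds(rng_seed: int, n: int = 2) -> list[int]:
    ss = np.random.SeedSequence(rng_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_paired_study(
    spec: PairedStudySpec,
) -> tuple[SuvImage, SuvImage, GroundTruthManifest]:
    """Simulate baseline and follow-up volumes plus their truth manifest.

    Both timepoints run the rasterize -> blur -> noise chain with
    independent noise seeds derived from the baseline ``rng_seed``.
    """
    base = spec.baseline
    seed_pre, seed_post = _derive_seeds(base.rng_seed, 2)
    scale = {
        lid: 1.0 + rd / 100.0 for lid, rd in spec.true_rd_percent.items()
    }
    post_spec = base.with_scaled_lesions(scale)

    pre = simulate_phantom(base, seed=seed_pre)
    post = simulate_phantom(post_spec, seed=seed_post)

    truths = []
    for les in base.lesions:
        rd = spec.true_rd_percent.get(les.lesion_id, 0.0)
        center_idx = np.floor(base.grid.world_to_index(les.center_mm) + 0.5).astype(int)
        center_idx = np.clip(center_idx, 0, np.asarray(base.grid.shape) - 1)
        truths.append(
            LesionTruth(
                lesion_id=les.lesion_id,
                true_suv_pre=les.true_suv,
                true_suv_post=les.true_suv * (1.0 + rd / 100.0),
                true_rd_percent=rd,
                true_volume_ml=les.true_volume_ml,
                center_voxel=tuple(int(i) for i in center_idx),
                semi_axes_mm=les.semi_axes_mm,
            )
        )
    return pre, post, GroundTruthManifest(lesions=truths)
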