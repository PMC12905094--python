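"""The bundled synthetic response cohort.

A paired pre/post phantom study with 16 evaluable spherical lesions laid
out on a torso-scale grid (96 x 96 x 64 voxels at 4-mm isotropic spacing),
emulating the size of the trial's evaluable-target pool:

* true relative differences: ten lesions at -40% (responders), five at
  +20% (indeterminate) and one at +50% (progression);
* baseline true SUV 10 g/mL for half the lesions (FDG-avid after imaging)
  and 5 g/mL for the other half, over a 1.0 g/mL background;
* lesion radii cycle through 8, 10, 12 and 14 mm — all above the 1.728-mL
  evaluability threshold;
* degradation by 4-mm-FWHM Gaussian scanner blur and additive Gaussian
  noise of 0.1 SUV.

These are the fixed study conditions used by the end-to-end recovery
checks; they are not tuning knobs.
"""

from __future__ import annotations

import numpy as np

from .delineation import SeedInit
from .image import GridSpec
from .phantom import GroundTruthManifest, LesionSpec, PairedStudySpec, PhantomSpec

__all__ = [
    "demo_cohort_spec",
    "seed_inits_from_truth",
    "replicate_category_counts",
    "category_recovery_rate",
    "TRUE_CATEGORY_COUNTS",
]

#: Category counts implied by the cohort's true relative differences.
TRUE_CATEGORY_COUNTS = {"response": 10, "indeterminate": 5, "progression": 1}

_RADII_MM = (8.0, 10.0, 12.0, 14.0)
_BACKGROUND_SUV = 1.0
_AVID_TRUE_SUV = 10.0
_NONAVID_TRUE_SUV = 5.0
_NOISE_SIGMA_SUV = 0.1
_BLUR_FWHM_MM = 4.0


def demo_cohort_spec(seed: int = 0) -> PairedStudySpec:
    """Paired-study specification of the 16-lesion synthetic cohort."""
    grid = GridSpec(shape=(96, 96, 64), spacing_mm=4.0)
    xy = (48.0, 144.0, 240.0, 336.0)
    z = 128.0
    lesions = []
    true_rd: dict[int, float] = {}
    for lid in range(1, 17):
        row, col = divmod(lid - 1, 4)
        radius = _RADII_MM[(lid - 1) % 4]
        true_suv = _AVID_TRUE_SUV if lid % 2 == 1 else _NONAVID_TRUE_SUV
        lesions.append(
            LesionSpec(
                lesion_id=lid,
                center_mm=(xy[row], xy[col], z),
                semi_axes_mm=(radius, radius, radius),
                true_suv=true_suv,
            )
        )
        if lid <= 10:
            true_rd[lid] = -40.0
        elif lid <= 15:
            true_rd[lid] = 20.0
        else:
            true_rd[lid] = 50.0
    baseline = PhantomSpec(
        grid=grid,
        background_suv=_BACKGROUND_SUV,
        lesions=tuple(lesions),
        blur_fwhm_mm=_BLUR_FWHM_MM,
        noise_sigma_suv=_NOISE_SIGMA_SUV,
        rng_seed=int(seed),
    )
    return PairedStudySpec(baseline=baseline, true_rd_percent=true_rd)


def seed_inits_from_truth(
    manifest: GroundTruthManifest, grid: GridSpec
) -> dict[int, SeedInit]:
    """Operator seed clicks derived from ground truth.

    Emulates clicking each lesion's center voxel and dragging along its
    longest axis out to the lesion boundary (rounded to whole voxels, at
    least one voxel).
    """
    inits = {}
    for t in manifest.lesions:
        axis = int(np.argmax(t.semi_axes_mm))
        steps = max(1, round(t.semi_axes_mm[axis] / grid.spacing[axis]))
        drag = list(t.center_voxel)
        drag[axis] += steps
        if drag[axis] >= grid.shape[axis]:
            drag[axis] = t.center_voxel[axis] - steps
        inits[t.lesion_id] = SeedInit(
            seed_voxel=t.center_voxel, drag_voxel=tuple(drag)
        )
    return inits


def replicate_category_counts(seed: int) -> dict[str, int]:
    """One end-to-end cohort replicate: SUV_mean category counts.

    Simulates the paired study at the given seed, delineates every lesion
    on the baseline image, freezes the masks, computes the SUV_mean
    relative difference and classifies it.  Only evaluable targets are
    counted, matching the cohort summary rules.
    """
    from .delineation import delineate
    from .phantom import generate_paired_study
    from .quantify import compute_lesion_metrics
    from .response import classify, relative_difference

    spec = demo_cohort_spec(seed=seed)
    pre, post, truth = generate_paired_study(spec)
    inits = seed_inits_from_truth(truth, pre.grid)
    counts = {cat: 0 for cat in TRUE_CATEGORY_COUNTS}
    for t in truth.lesions:
        mask = delineate(pre, inits[t.lesion_id], lesion_id=t.lesion_id).mask
        m_pre = compute_lesion_metrics(pre, mask, t.lesion_id)
        if not m_pre.evaluable:
            continue
        m_post = compute_lesion_metrics(post, mask, t.lesion_id)
        rd = relative_difference(m_pre.suv_mean, m_post.suv_mean)
        counts[classify(rd)] += 1
    return counts


def category_recovery_rate(n_replicates: int = 100, base_seed: int = 0) -> float:
    """Fraction of seeded replicates whose category counts match the truth."""
    hits = 0
    for i in range(n_replicates):
        if replicate_category_counts(base_seed + i) == TRUE_CATEGORY_COUNTS:
            hits += 1
    return hits / n_replicates
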