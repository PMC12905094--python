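"""Simulate a paired pre/post PET phantom with known lesion truth.

Builds a small torso-slab grid with two spherical lesions, applies 4-mm
scanner blur and mild noise, and prints the ground truth alongside the
voxel values actually observed at each lesion center.
"""

import numpy as np

from petresponse import (
    GridSpec,
    LesionSpec,
    PairedStudySpec,
    PhantomSpec,
    generate_paired_study,
)

grid = GridSpec(shape=(48, 48, 32), spacing_mm=4.0)
lesions = (
    LesionSpec(lesion_id=1, center_mm=(70.0, 70.0, 65.0), semi_axes_mm=(10.0,) * 3, true_suv=10.0),
    LesionSpec(lesion_id=2, center_mm=(130.0, 120.0, 65.0), semi_axes_mm=(8.0,) * 3, true_suv=6.0),
)
baseline = PhantomSpec(
    grid=grid,
    background_suv=1.0,
    lesions=lesions,
    blur_fwhm_mm=4.0,
    noise_sigma_suv=0.1,
    rng_seed=0,
)
# lesion 1 loses 40% of its uptake after treatment, lesion 2 gains 20%
spec = PairedStudySpec(baseline=baseline, true_rd_percent={1: -40.0, 2: 20.0})

pre, post, truth = generate_paired_study(spec)

print("lesion  true_pre  true_post  true_RD%  vol_mL  observed_pre  observed_post")
for t in truth.lesions:
    cv = t.center_voxel
    print(
        f"{t.lesion_id:>6}  {t.true_suv_pre:8.2f}  {t.true_suv_post:9.2f}"
        f"  {t.true_rd_percent:8.1f}  {t.true_volume_ml:6.2f}"
        f"  {pre.values[cv]:12.3f}  {post.values[cv]:13.3f}"
    )
print(
    "\nObserved center values sit close to the true SUVs because both lesions"
    "\nare large relative to the 4-mm blur; the residual gap is the partial"
    "\nvolume effect plus noise that the downstream stages must cope with."
)
print(f"background mean (should be ~1.0): {np.median(pre.values):.3f}")
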