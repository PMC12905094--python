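"""Recover a small lesion's true uptake with damped Richardson-Lucy PVC.

An 8-mm-diameter lesion at true SUV 10 loses ~15% of its apparent maximum
to the 4-mm scanner blur.  Five damped RL iterations against the matching
Gaussian PSF restore most of it.
"""

from petresponse import (
    GridSpec,
    LesionSpec,
    PhantomSpec,
    RlConfig,
    make_gaussian_psf,
    rasterize_lesions,
    richardson_lucy_damped,
    suv_max,
)
from petresponse.phantom import simulate_phantom

grid = GridSpec(shape=(32, 32, 32), spacing_mm=4.0)
lesion = LesionSpec(lesion_id=1, center_mm=(63.0,) * 3, semi_axes_mm=(4.0,) * 3, true_suv=10.0)
spec = PhantomSpec(grid=grid, background_suv=1.0, lesions=(lesion,), blur_fwhm_mm=4.0)
observed = simulate_phantom(spec)  # noise-free, blur only

psf = make_gaussian_psf(fwhm_mm=4.0, spacing_mm=4.0, size=11)
mask = rasterize_lesions(PhantomSpec(grid=grid, background_suv=0.0, lesions=(lesion,))).values > 5

print("iterations  SUV_max   (true = 10.00)")
print(f"{'observed':>10}  {suv_max(observed, mask):7.3f}")
for k in (1, 2, 3, 5):
    corrected = richardson_lucy_damped(observed, psf, RlConfig(iterations=k, damping=0.1))
    print(f"{k:>10}  {suv_max(corrected, mask):7.3f}")
print(
    "\nThe maximum climbs back toward the true SUV with each iteration;"
    "\nthe damping threshold (0.1 SUV) attenuates updates where residuals"
    "\nare small so noise is not amplified on real, noisy scans."
)
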