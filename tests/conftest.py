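import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petresponse import GridSpec, LesionSpec, PhantomSpec, SuvImage
from petresponse.phantom import simulate_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def grid4():
    """Small isotropic 4-mm grid, the spacing used throughout the analysis."""
    return GridSpec(shape=(32, 32, 32), spacing_mm=4.0)


@pytest.fixture
def sphere_phantom(grid4):
    """Factory for single-sphere phantoms on the 4-mm grid."""

    def make(
        radius_mm=10.0,
        true_suv=10.0,
        background=1.0,
        center_mm=(63.0, 63.0, 63.0),
        blur_fwhm_mm=0.0,
        noise_sigma=0.0,
        seed=0,
    ):
        lesion = LesionSpec(
            lesion_id=1,
            center_mm=center_mm,
            semi_axes_mm=(radius_mm, radius_mm, radius_mm),
            true_suv=true_suv,
        )
        spec = PhantomSpec(
            grid=grid4,
            background_suv=background,
            lesions=(lesion,),
            blur_fwhm_mm=blur_fwhm_mm,
            noise_sigma_suv=noise_sigma,
            rng_seed=seed,
        )
        return spec, simulate_phantom(spec)

    return make


@pytest.fixture
def random_lesion_image():
    """Factory for small random images with a random blob mask (seeded)."""

    def make(seed):
        rng = np.random.default_rng(seed)
        grid = GridSpec(shape=(16, 16, 16), spacing_mm=4.0)
        values = rng.uniform(0.5, 2.0, size=grid.shape)
        center = rng.integers(4, 12, size=3)
        hot = rng.uniform(5.0, 20.0)
        ii, jj, kk = np.indices(grid.shape)
        d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2
        mask = d2 <= rng.integers(2, 12)
        values[mask] += hot * rng.uniform(0.5, 1.0, size=int(mask.sum()))
        return SuvImage(values=values, grid=grid), mask

    return make
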