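import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petresponse import (
    GridSpec,
    SuvImage,
    compute_lesion_metrics,
    is_evaluable,
    is_fdg_avid,
    sphere_diameter_cm,
    sphere_volume_ml,
    suv_from_activity,
    suv_max,
    suv_mean,
    suv_peak,
    volume_ml,
)


class TestSuvFromActivity:
    def test_normalization_identity(self):
        # concentration equal to dose/mass everywhere -> SUV 1.0
        dose_mbq, mass_kg = 370.0, 70.0
        conc = np.full((4, 4, 4), dose_mbq * 1000.0 / (mass_kg * 1000.0))
        assert np.allclose(suv_from_activity(conc, dose_mbq, mass_kg), 1.0)

    def test_unit_arithmetic(self):
        suv = suv_from_activity(np.array([5.0]), 370.0, 70.0)
        assert suv[0] == pytest.approx(5.0 / (370000.0 / 70000.0), rel=1e-12)
        assert suv[0] == pytest.approx(0.9459, abs=1e-4)

    def test_linear_in_mass(self):
        conc = np.array([3.0])
        a = suv_from_activity(conc, 370.0, 70.0)
        b = suv_from_activity(conc, 370.0, 140.0)
        assert b[0] == pytest.approx(2.0 * a[0], rel=1e-12)

    @pytest.mark.parametrize("dose,mass", [(0.0, 70.0), (370.0, 0.0), (-1.0, 70.0)])
    def test_nonpositive_dose_or_mass_rejected(self, dose, mass):
        with pytest.raises(ValueError):
            suv_from_activity(np.ones((2, 2, 2)), dose, mass)


class TestMaxMean:
    def test_uniform_lesion(self, grid4):
        values = np.ones(grid4.shape)
        mask = np.zeros(grid4.shape, bool)
        mask[10:13, 10:13, 10:13] = True
        values[mask] = 4.2
        img = SuvImage(values=values, grid=grid4)
        assert suv_max(img, mask) == 4.2
        assert suv_mean(img, mask) == pytest.approx(4.2)

    def test_hand_arithmetic(self, grid4):
        values = np.ones(grid4.shape)
        mask = np.zeros(grid4.shape, bool)
        for v, idx in zip((1.0, 2.0, 9.0), ((5, 5, 5), (5, 5, 6), (5, 5, 7))):
            values[idx] = v
            mask[idx] = True
        img = SuvImage(values=values, grid=grid4)
        assert suv_max(img, mask) == 9.0
        assert suv_mean(img, mask) == 4.0

    def test_empty_mask_rejected(self, grid4):
        img = SuvImage(values=np.ones(grid4.shape), grid=grid4)
        with pytest.raises(ValueError, match="empty"):
            suv_max(img, np.zeros(grid4.shape, bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_never_exceeds_max(self, random_lesion_image, seed):
        img, mask = random_lesion_image(seed)
        assert suv_mean(img, mask) <= suv_max(img, mask)


class TestSuvPeak:
    def test_large_uniform_lesion_peak_equals_value(self, grid4):
        values = np.ones(grid4.shape)
        mask = np.zeros(grid4.shape, bool)
        mask[8:24, 8:24, 8:24] = True  # 64 mm across, >> 12.4-mm sphere
        values[mask] = 7.7
        img = SuvImage(values=values, grid=grid4)
        assert suv_peak(img, mask) == pytest.approx(7.7, abs=1e-9)

    def test_single_hot_voxel_19_voxel_sphere(self, grid4):
        # 1-mL sphere radius 6.2035 mm on a 4-mm grid captures the center,
        # 6 face neighbors and 12 edge neighbors = 19 voxels
        values = np.ones(grid4.shape)
        values[16, 16, 16] = 100.0
        mask = np.zeros(grid4.shape, bool)
        mask[16, 16, 16] = True
        img = SuvImage(values=values, grid=grid4)
        assert suv_peak(img, mask) == pytest.approx((100.0 + 18.0) / 19.0, rel=1e-12)

    def test_absent_on_too_coarse_grid(self):
        grid = GridSpec(shape=(8, 8, 8), spacing_mm=16.0)
        values = np.ones(grid.shape)
        values[4, 4, 4] = 10.0
        mask = np.zeros(grid.shape, bool)
        mask[4, 4, 4] = True
        img = SuvImage(values=values, grid=grid)
        assert suv_peak(img, mask) is None

    def test_noise_free_plateau_recovers_true_suv(self, sphere_phantom):
        # lesion diameter (40 mm) >= 3x the sphere diameter: peak = true SUV
        spec, img = sphere_phantom(radius_mm=20.0, center_mm=(63.0, 63.0, 63.0))
        mask = img.values > 5.0
        assert suv_peak(img, mask) == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, random_lesion_image, seed):
        img, mask = random_lesion_image(seed)
        r = (3.0 * 1.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        # oracle: brute-force voxel-center distances over the whole grid,
        # sphere centered at the hottest masked voxel (lowest linear index)
        lin = np.flatnonzero(mask.ravel())
        hot = lin[np.argmax(img.values.ravel()[lin])]
        ci, cj, ck = np.unravel_index(hot, mask.shape)
        ii, jj, kk = np.indices(mask.shape)
        d2 = sum(
            ((a - c) * s) ** 2
            for a, c, s in zip((ii, jj, kk), (ci, cj, ck), img.grid.spacing)
        )
        oracle = img.values[d2 <= r**2].mean()
        assert suv_peak(img, mask) == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_to_shuffling_outside_mask_and_sphere(self, random_lesion_image, seed):
        img, mask = random_lesion_image(seed)
        base = (
            suv_max(img, mask),
            suv_mean(img, mask),
            suv_peak(img, mask),
        )
        r = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        lin = np.flatnonzero(mask.ravel())
        hot = np.unravel_index(lin[np.argmax(img.values.ravel()[lin])], mask.shape)
        ii, jj, kk = np.indices(mask.shape)
        d2 = sum(
            ((a - c) * s) ** 2
            for a, c, s in zip((ii, jj, kk), hot, img.grid.spacing)
        )
        protected = mask | (d2 <= r**2)
        rng = np.random.default_rng(seed)
        values = img.values.copy()
        outside = ~protected
        values[outside] = rng.permutation(values[outside])
        shuffled = SuvImage(values=values, grid=img.grid)
        assert (
            suv_max(shuffled, mask),
            suv_mean(shuffled, mask),
            suv_peak(shuffled, mask),
        ) == base

    def test_maximizing_placement_never_below_default(self, random_lesion_image):
        img, mask = random_lesion_image(1)
        assert suv_peak(img, mask, maximize_sphere_mean=True) >= suv_peak(img, mask)


class TestVolumeAndFilters:
    def test_27_voxels_at_4mm_is_1_728_ml(self):
        grid = GridSpec(shape=(8, 8, 8), spacing_mm=4.0)
        mask = np.zeros(grid.shape, bool)
        mask[2:5, 2:5, 2:5] = True
        assert volume_ml(mask, grid) == 1.728

    def test_single_voxel_volumes(self):
        grid4 = GridSpec(shape=(4, 4, 4), spacing_mm=4.0)
        grid1 = GridSpec(shape=(12, 12, 12), spacing_mm=1.0)
        m4 = np.zeros(grid4.shape, bool)
        m4[0, 0, 0] = True
        assert volume_ml(m4, grid4) == pytest.approx(0.064)
        m1 = np.zeros(grid1.shape, bool)
        m1[:10, :10, :10] = True
        assert volume_ml(m1, grid1) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "vol,expected", [(0.1, False), (1.728, True), (10.0, True), (1.7279, False)]
    )
    def test_evaluability_boundary_inclusive(self, vol, expected):
        assert is_evaluable(vol) is expected

    @pytest.mark.parametrize(
        "smax,expected", [(7.5, True), (7.4999, False), (20.0, True), (0.0, False)]
    )
    def test_avidity_boundary_inclusive(self, smax, expected):
        assert is_fdg_avid(smax) is expected

    @given(
        vol=st.floats(0.01, 100.0),
        bump=st.floats(0.0, 50.0),
    )
    def test_filters_monotone(self, vol, bump):
        if is_evaluable(vol):
            assert is_evaluable(vol + bump)
        if is_fdg_avid(vol):
            assert is_fdg_avid(vol + bump)

    def test_compute_lesion_metrics_consistency(self, random_lesion_image):
        img, mask = random_lesion_image(3)
        m = compute_lesion_metrics(img, mask, lesion_id=7)
        assert m.lesion_id == 7
        assert m.suv_mean <= m.suv_max
        assert m.evaluable == (m.volume_ml >= 1.728)
        assert m.fdg_avid == (m.suv_max >= 7.5)


class TestSphereGeometry:
    def test_15mm_sphere_volume(self):
        assert sphere_volume_ml(15.0) == pytest.approx(1.767, abs=0.005)

    def test_1ml_sphere_diameter(self):
        assert sphere_diameter_cm(1.0) == pytest.approx(1.24, abs=0.005)
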