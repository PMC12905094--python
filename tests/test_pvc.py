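import numpy as np
import pytest
from scipy import ndimage

from petresponse import (
    GridSpec,
    LesionSpec,
    PhantomSpec,
    PsfKernel,
    RlConfig,
    SuvImage,
    UnsupportedParameterError,
    apply_pvc_to_study,
    make_gaussian_psf,
    rasterize_lesions,
    richardson_lucy_damped,
    suv_max,
)
from petresponse.phantom import simulate_phantom
from petresponse.pvc import _convolve_replicate


def delta_psf(size=11):
    w = np.zeros((size, size, size))
    w[size // 2, size // 2, size // 2] = 1.0
    return PsfKernel(weights=w, fwhm_mm=0.0, spacing_mm=(4.0, 4.0, 4.0))


def small_lesion_study(grid4, diameter_mm=8.0, noise=0.0, seed=0):
    r = diameter_mm / 2.0
    lesion = LesionSpec(1, (63.0, 63.0, 63.0), (r, r, r), 10.0)
    spec = PhantomSpec(
        grid=grid4,
        background_suv=1.0,
        lesions=(lesion,),
        blur_fwhm_mm=4.0,
        noise_sigma_suv=noise,
        rng_seed=seed,
    )
    return spec, simulate_phantom(spec)


def reference_rl_1d(y, kernel, iterations, damping):
    """Hand-rolled 1-D damped RL recursion (independent oracle)."""
    x = y.copy()
    pad = len(kernel) // 2

    def conv(a, k):
        return np.convolve(np.pad(a, pad, mode="edge"), k, mode="valid")

    for _ in range(iterations):
        y_hat = np.maximum(conv(x, kernel), 1e-12)
        ratio = y / y_hat
        if damping > 0:
            u = np.minimum(((y - y_hat) / damping) ** 2, 1.0)
            w = 1.0 - (1.0 - u) ** 2
            ratio = 1.0 + w * (ratio - 1.0)
        x = np.clip(x * conv(ratio, kernel[::-1]), 0.0, None)
    return x


class TestPsf:
    def test_weights_sum_to_one(self):
        psf = make_gaussian_psf(4.0, 4.0)
        assert abs(psf.weights.sum() - 1.0) <= 1e-12
        assert psf.weights.shape == (11, 11, 11)

    def test_sigma_fwhm_relation_on_fine_grid(self):
        # on a 1-mm grid the weight 2 mm from center is half the central one
        psf = make_gaussian_psf(4.0, 1.0, size=11)
        center = psf.weights[5, 5, 5]
        at_2mm = psf.weights[7, 5, 5]
        assert at_2mm == pytest.approx(0.5 * center, rel=0.02)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            make_gaussian_psf(4.0, 4.0, size=10)

    def test_central_symmetry(self):
        psf = make_gaussian_psf(4.0, (4.0, 4.0, 4.0), size=7)
        assert np.allclose(psf.weights, psf.weights[::-1, ::-1, ::-1])


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self, grid4):
        _, img = small_lesion_study(grid4, diameter_mm=16.0)
        out = richardson_lucy_damped(img, delta_psf(), RlConfig(iterations=4, damping=0.0))
        assert np.allclose(out.values, img.values, atol=1e-9)

    def test_uniform_image_is_fixed_point(self, grid4):
        img = SuvImage(values=np.full(grid4.shape, 3.0), grid=grid4)
        psf = make_gaussian_psf(4.0, 4.0)
        out = richardson_lucy_damped(img, psf, RlConfig(iterations=5, damping=0.0))
        assert np.allclose(out.values, 3.0, atol=1e-9)

    def test_negative_input_rejected(self, grid4):
        img = SuvImage(values=np.ones(grid4.shape), grid=grid4)
        img.values[0, 0, 0] = 1.0  # SuvImage forbids negatives; bypass check
        bad = img.values.copy()
        bad[1, 1, 1] = -0.5
        img.values = bad
        with pytest.raises(ValueError, match="non-negative"):
            richardson_lucy_damped(img, make_gaussian_psf(4.0, 4.0), RlConfig())

    def test_zero_iterations_is_identity(self, grid4):
        _, img = small_lesion_study(grid4)
        out = richardson_lucy_damped(img, make_gaussian_psf(4.0, 4.0), RlConfig(iterations=0))
        assert np.array_equal(out.values, img.values)

    @pytest.mark.parametrize("damping", [0.0, 0.1])
    def test_matches_hand_rolled_1d_recursion(self, damping):
        rng = np.random.default_rng(0)
        signal = np.abs(rng.normal(5.0, 1.0, 64))
        kernel = np.exp(-0.5 * (np.arange(-5, 6) / 1.7) ** 2)
        kernel /= kernel.sum()
        grid = GridSpec(shape=(64, 1, 1), spacing_mm=4.0)
        img = SuvImage(values=signal.reshape(64, 1, 1), grid=grid)
        psf = PsfKernel(weights=kernel.reshape(11, 1, 1), fwhm_mm=4.0, spacing_mm=(4.0, 4.0, 4.0))
        mine = richardson_lucy_damped(img, psf, RlConfig(iterations=5, damping=damping))
        oracle = reference_rl_1d(signal, kernel, 5, damping)
        assert np.abs(mine.values.ravel() - oracle).max() < 1e-10

    def test_max_recovery_monotone_on_blurred_small_sphere(self, grid4):
        # noise-free 8-mm-diameter sphere: the undamped max climbs toward
        # the true SUV and ends above the blurred max
        _, img = small_lesion_study(grid4, diameter_mm=8.0)
        psf = make_gaussian_psf(4.0, 4.0)
        maxes = [img.values.max()]
        for k in range(1, 6):
            out = richardson_lucy_damped(img, psf, RlConfig(iterations=k, damping=0.0))
            maxes.append(out.values.max())
        assert all(b >= a - 1e-12 for a, b in zip(maxes, maxes[1:]))
        assert maxes[-1] > maxes[0]

    def test_kl_divergence_non_increasing_undamped(self, grid4):
        _, img = small_lesion_study(grid4, diameter_mm=12.0)
        psf = make_gaussian_psf(4.0, 4.0)
        y = img.values
        kl = []
        for k in range(5):
            x = richardson_lucy_damped(img, psf, RlConfig(iterations=k, damping=0.0)).values
            y_hat = np.maximum(_convolve_replicate(x, psf.weights), 1e-12)
            kl.append(float(np.sum(y * np.log(np.maximum(y, 1e-12) / y_hat) - y + y_hat)))
        assert all(b <= a + 1e-9 for a, b in zip(kl, kl[1:]))

    def test_damping_attenuates_mean_update(self, grid4):
        # larger damping threshold -> smaller mean |output - input| on a
        # noisy phantom (small residuals get attenuated updates)
        _, img = small_lesion_study(grid4, diameter_mm=12.0, noise=0.2, seed=3)
        psf = make_gaussian_psf(4.0, 4.0)
        devs = []
        for T in (0.0, 0.05, 0.1, 0.2, 0.5):
            out = richardson_lucy_damped(img, psf, RlConfig(iterations=5, damping=T))
            devs.append(np.abs(out.values - img.values).mean())
        assert all(b <= a + 1e-12 for a, b in zip(devs, devs[1:]))

    def test_non_negativity_preserved(self, grid4):
        _, img = small_lesion_study(grid4, diameter_mm=8.0, noise=0.2, seed=1)
        out = richardson_lucy_damped(img, make_gaussian_psf(4.0, 4.0), RlConfig())
        assert out.values.min() >= 0.0

    def test_subsample_other_than_one_unsupported(self):
        with pytest.raises(UnsupportedParameterError):
            RlConfig(subsample=2)


class TestApplyPvcToStudy:
    def _masks(self, grid4, diameter_mm=8.0):
        r = diameter_mm / 2.0
        lesion = LesionSpec(1, (63.0, 63.0, 63.0), (r, r, r), 10.0)
        mask_img = rasterize_lesions(
            PhantomSpec(grid=grid4, background_suv=0.0, lesions=(lesion,))
        )
        return {1: mask_img.values > 5.0}

    def test_delta_psf_leaves_metrics_unchanged(self, grid4):
        _, pre = small_lesion_study(grid4, diameter_mm=12.0)
        _, post = small_lesion_study(grid4, diameter_mm=12.0)
        masks = self._masks(grid4, 12.0)
        _, _, m_pre, m_post = apply_pvc_to_study(
            pre, post, masks, cfg=RlConfig(iterations=5, damping=0.0), psf=delta_psf()
        )
        assert m_pre[1].suv_max == pytest.approx(suv_max(pre, masks[1]), abs=1e-9)
        assert m_pre[1].volume_ml == m_post[1].volume_ml

    def test_partial_volume_bias_reduced_for_small_lesion(self, grid4):
        # 8-mm lesion: correction must bring SUV_max closer to the true 10
        _, pre = small_lesion_study(grid4, diameter_mm=8.0)
        masks = self._masks(grid4, 8.0)
        pre_pvc, _, m_pre, _ = apply_pvc_to_study(pre, pre, masks)
        raw_err = abs(suv_max(pre, masks[1]) - 10.0)
        pvc_err = abs(m_pre[1].suv_max - 10.0)
        assert pvc_err < raw_err

    def test_evaluability_flags_frozen(self, grid4):
        _, pre = small_lesion_study(grid4, diameter_mm=12.0)
        masks = self._masks(grid4, 12.0)
        _, _, m_pre, m_post = apply_pvc_to_study(pre, pre, masks)
        from petresponse import compute_lesion_metrics

        raw = compute_lesion_metrics(pre, masks[1], 1)
        assert m_pre[1].evaluable == raw.evaluable == m_post[1].evaluable

    def test_mismatched_grids_rejected(self, grid4):
        _, pre = small_lesion_study(grid4)
        other = GridSpec(shape=(16, 16, 16), spacing_mm=4.0)
        post = SuvImage(values=np.ones(other.shape), grid=other)
        with pytest.raises(ValueError, match="grid"):
            apply_pvc_to_study(pre, post, self._masks(grid4))
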