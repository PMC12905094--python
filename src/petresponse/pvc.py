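"""Partial-volume correction by damped Richardson-Lucy deconvolution.

The limited spatial resolution of PET blends signal from small hot lesions
into their surroundings (the partial volume effect), biasing SUV statistics
downward.  This module restores SUV volumes by iterative Richardson-Lucy
(RL) deconvolution against a 3-D Gaussian point-spread-function model, with
a residual-attenuation damping term that suppresses noise amplification.

Update rule, starting from ``x_0 = y`` (the observed image)::

    y_hat_k = C(x_k)                      # convolution with the PSF
    r_k     = 1 + w_k * (y / y_hat_k - 1) # damped ratio
    x_{k+1} = x_k * C_T(r_k)              # C_T: mirrored-kernel convolution

with the damping weight ``w_k = 1 - (1 - min(((y - y_hat_k)/T)^2, 1))^2``
for damping threshold ``T`` in SUV units (``w == 1`` when ``T == 0``,
recovering the classic undamped recursion).  Voxels whose residual is small
relative to ``T`` receive attenuated updates.  Convolutions use replicate
boundary padding, which makes a uniform image an exact fixed point.

Defaults: 5 iterations, damping 0.1 SUV, Gaussian PSF of 4-mm FWHM sampled
on an 11-voxel-per-axis kernel, no subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .image import SuvImage
from .phantom import FWHM_TO_SIGMA
from .quantify import LesionMetrics, compute_lesion_metrics

__all__ = [
    "PsfKernel",
    "RlConfig",
    "UnsupportedParameterError",
    "make_gaussian_psf",
    "richardson_lucy_damped",
    "apply_pvc_to_study",
]

_EPS = 1e-12


class UnsupportedParameterError(ValueError):
    """A configuration value outside the implemented parameter space."""


@dataclass(frozen=True)
class PsfKernel:
    """Discrete PSF: non-negative weights summing to one, odd per-axis size."""

    weights: np.ndarray
    fwhm_mm: float
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 3 or any(n % 2 == 0 for n in w.shape):
            raise ValueError("PSF must be 3-D with odd size per axis")
        if np.any(w < 0):
            raise ValueError("PSF weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("PSF weights must sum to 1 within 1e-12")
        if not np.allclose(w, w[::-1, ::-1, ::-1]):
            raise ValueError("PSF must be centrally symmetric")
        object.__setattr__(self, "weights", w)

    @property
    def mirrored(self) -> np.ndarray:
        return self.weights[::-1, ::-1, ::-1]

    @property
    def is_delta(self) -> bool:
        center = tuple(n // 2 for n in self.weights.shape)
        return bool(self.weights[center] == 1.0)


@dataclass(frozen=True)
class RlConfig:
    """Richardson-Lucy configuration; the defaults are the analysis settings."""

    iterations: int = 5
    damping: float = 0.1  # SUV units; 0 disables damping
    subsample: int = 1

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.damping < 0:
            raise ValueError("damping must be non-negative")
        if self.subsample != 1:
            raise UnsupportedParameterError(
                "only subsample=1 (no subsampling) is implemented"
            )


def make_gaussian_psf(
    fwhm_mm: float, spacing_mm, size: int = 11
) -> PsfKernel:
    """Separable 3-D Gaussian PSF sampled at voxel centers.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis; the sampled kernel is
    renormalised to unit sum.  ``size`` is the per-axis kernel extent in
    voxels and must be odd.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if size % 2 == 0 or size < 1:
        raise ValueError("kernel size must be a positive odd integer")
    spacing = np.atleast_1d(np.asarray(spacing_mm, dtype=float))
    if spacing.size == 1:
        spacing = np.repeat(spacing, 3)
    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    half = size // 2
    axes = []
    for s in spacing:
        x = np.arange(-half, half + 1) * s
        axes.append(np.exp(-0.5 * (x / sigma_mm) ** 2))
    w = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    w /= w.sum()
    return PsfKernel(weights=w, fwhm_mm=float(fwhm_mm), spacing_mm=tuple(spacing))


def _convolve_replicate(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolution under replicate (edge) padding.

    Implemented as FFT convolution on an edge-padded array; identical to
    direct spatial convolution up to float rounding.
    """
    pad = [(n // 2, n // 2) for n in kernel.shape]
    padded = np.pad(values, pad, mode="edge")
    out = fftconvolve(padded, kernel, mode="valid")
    return out


def richardson_lucy_damped(
    image: SuvImage, psf: PsfKernel, cfg: RlConfig | None = None
) -> SuvImage:
    """Deconvolve an SUV volume with the damped RL recursion.

    The observed image is both the data term ``y`` and the initial estimate
    ``x_0``.  Output is clipped at zero (the multiplicative update preserves
    non-negativity exactly; clipping only removes FFT rounding dust).
    """
    if cfg is None:
        cfg = RlConfig()
    if np.any(image.values < 0):
        raise ValueError("input image must be non-negative")

    y = image.values
    x = y.copy()
    kernel = psf.weights
    kernel_t = psf.mirrored
    T = cfg.damping

    for _ in range(cfg.iterations):
        y_hat = _convolve_replicate(x, kernel)
        y_hat = np.maximum(y_hat, _EPS)  # stabilize voxels predicted ~0
        ratio = y / y_hat
        if T > 0:
            u = np.minimum(((y - y_hat) / T) ** 2, 1.0)
            w = 1.0 - (1.0 - u) ** 2
            ratio = 1.0 + w * (ratio - 1.0)
        x = x * _convolve_replicate(ratio, kernel_t)
        x = np.clip(x, 0.0, None)
    return image.with_values(x)


def apply_pvc_to_study(
    pre: SuvImage,
    post: SuvImage,
    masks: dict[int, np.ndarray],
    cfg: RlConfig | None = None,
    psf: PsfKernel | None = None,
) -> tuple[SuvImage, SuvImage, dict[int, LesionMetrics], dict[int, LesionMetrics]]:
    """Correct both timepoints and recompute metrics on frozen contours.

    The same PSF and configuration are applied to the whole pre and post
    volumes; the baseline masks are reused, so volumes and evaluability
    flags are unchanged by correction.

    Returns ``(pre_pvc, post_pvc, metrics_pre, metrics_post)`` with metrics
    keyed by lesion id.
    """
    if pre.shape != post.shape or pre.grid != post.grid:
        raise ValueError("pre and post images must share a grid")
    if psf is None:
        psf = make_gaussian_psf(4.0, pre.grid.spacing_mm)
    if cfg is None:
        cfg = RlConfig()
    pre_pvc = richardson_lucy_damped(pre, psf, cfg)
    post_pvc = richardson_lucy_damped(post, psf, cfg)
    metrics_pre = {
        lid: compute_lesion_metrics(pre_pvc, m, lesion_id=lid) for lid, m in masks.items()
    }
    metrics_post = {
        lid: compute_lesion_metrics(post_pvc, m, lesion_id=lid) for lid, m in masks.items()
    }
    return pre_pvc, post_pvc, metrics_pre, metrics_post
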