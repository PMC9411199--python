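"""Illumination correction, dF/F computation, and temporal denoising.

Absolute fluorescence in coronal connective images falls off along the
medial-lateral (x) axis, likely from scattering by displaced thoracic
organs. The correction fits a straight line to the central portion of the
x-axis intensity profile of the temporal-mean image and divides every
column by it. Because a pixel's time series and its baseline are scaled by
the same factor, dF/F is exactly invariant to this correction; it matters
only for visualizing raw fluorescence.

dF/F is (F - F0) / F0 with a per-pixel baseline F0 defined as the minimum,
across all trials, of the spatially (sigma = 10 px) and temporally
(10-sample boxcar) smoothed fluorescence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datatypes import BaselineImage, FrameStack

__all__ = [
    "PhotometryParams",
    "IlluminationProfile",
    "fit_illumination_profile",
    "apply_illumination_correction",
    "compute_baseline",
    "compute_dff",
    "temporal_denoise",
]


@dataclass
class PhotometryParams:
    median_kernel: tuple[int, int] = (71, 91)   # (y, x) pixels
    profile_sigma: float = 3.0                  # px, low-pass before profile fit
    central_width: int = 200                    # columns used for the line fit
    baseline_spatial_sigma: float = 10.0        # px
    baseline_temporal_window: int = 10          # samples (~0.6 s at 16 Hz)
    denoise_half_window: int = 30               # frames each side (~2 s at 16 Hz)

    def __post_init__(self) -> None:
        if any(k <= 0 or k % 2 == 0 for k in self.median_kernel):
            raise ValueError("median kernel dims must be odd and positive")
        if min(self.profile_sigma, self.baseline_spatial_sigma) <= 0:
            raise ValueError("sigmas must be positive")
        if self.baseline_temporal_window < 1 or self.denoise_half_window < 1:
            raise ValueError("windows must be positive")


@dataclass
class IlluminationProfile:
    """Straight-line model of the x-axis gain, normalized to 1 at center."""

    gain: np.ndarray        # per-column multiplier
    fit_slope: float        # gain change per pixel
    fit_intercept: float    # gain at x = 0
    central_width: int = 200


def fit_illumination_profile(
    mean_image: np.ndarray, params: PhotometryParams | None = None
) -> IlluminationProfile:
    """Fit the left-right illumination gradient of a temporal-mean image.

    The mean image is median filtered then Gaussian filtered to remove
    individual-neuron features, averaged across y to a 1-D x profile, and
    a least-squares line is fit to the most central ``central_width``
    columns. The resulting line, normalized to 1 at the image center, is
    the per-column gain.
    """
    params = params or PhotometryParams()
    img = np.asarray(mean_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2-D mean image")
    h, w = img.shape
    if w <= params.central_width:
        raise ValueError(
            f"image width {w} must exceed central_width {params.central_width}"
        )
    kernel = (min(params.median_kernel[0], h), min(params.median_kernel[1], w))
    smoothed = ndimage.median_filter(img, size=kernel, mode="reflect")
    smoothed = ndimage.gaussian_filter(smoothed, params.profile_sigma, mode="reflect")
    profile = smoothed.mean(axis=0)

    center = w // 2
    x0 = center - params.central_width // 2
    cols = np.arange(x0, x0 + params.central_width)
    slope, intercept = np.polyfit(cols, profile[cols], deg=1)

    line = intercept + slope * np.arange(w)
    value_at_center = intercept + slope * center
    if value_at_center <= 0:
        raise ValueError("degenerate illumination fit (non-positive at center)")
    gain = line / value_at_center
    return IlluminationProfile(
        gain=gain,
        fit_slope=slope / value_at_center,
        fit_intercept=intercept / value_at_center,
        central_width=params.central_width,
    )


def apply_illumination_correction(
    stack: FrameStack, profile: IlluminationProfile
) -> FrameStack:
    """Divide every column by the fitted gain line.

    Refuses degenerate fits whose line crosses zero inside the frame.
    dF/F computed from the corrected stack equals dF/F from the raw
    stack because baseline and signal are scaled identically.
    """
    w = stack.shape[2]
    if profile.gain.shape[0] < w:
        raise ValueError("profile does not cover stack width")
    gain = profile.gain[:w]
    if np.any(gain <= 0):
        raise ValueError("illumination line non-positive inside frame; refusing")
    return stack.copy_with(stack.data / gain[None, None, :])


def _boxcar_time(data: np.ndarray, window: int) -> np.ndarray:
    """Centered temporal boxcar with edge truncation (renormalized)."""
    kernel = np.ones(window) / window
    num = ndimage.convolve1d(data, kernel, axis=0, mode="constant", cval=0.0)
    norm = ndimage.convolve1d(
        np.ones(data.shape[0]), kernel, mode="constant", cval=0.0
    )
    return num / norm[:, None, None]


def compute_baseline(
    trials: list[FrameStack], params: PhotometryParams | None = None
) -> BaselineImage:
    """Per-pixel baseline F0: the minimum over all frames of all trials of
    the spatially and temporally smoothed fluorescence, floored at
    epsilon = 1e-6 times the global maximum intensity."""
    params = params or PhotometryParams()
    if not trials:
        raise ValueError("need at least one trial")
    shape = trials[0].shape[1:]
    if any(t.shape[1:] != shape for t in trials):
        raise ValueError("all trials must share frame shape")

    global_max = max(float(t.data.max()) for t in trials)
    epsilon = 1e-6 * global_max if global_max > 0 else 1e-12

    f0 = np.full(shape, np.inf)
    for trial in trials:
        smoothed = ndimage.gaussian_filter(
            trial.data,
            sigma=(0, params.baseline_spatial_sigma, params.baseline_spatial_sigma),
            mode="reflect",
        )
        smoothed = _boxcar_time(smoothed, params.baseline_temporal_window)
        f0 = np.minimum(f0, smoothed.min(axis=0))
    return BaselineImage(f0=np.maximum(f0, epsilon), epsilon=epsilon)


def compute_dff(stack: FrameStack, baseline: BaselineImage) -> FrameStack:
    """dF/F = (F - F0) / F0, elementwise. Bounded below by -1."""
    if stack.shape[1:] != baseline.f0.shape:
        raise ValueError("stack and baseline shapes differ")
    return stack.copy_with((stack.data - baseline.f0) / baseline.f0)


def temporal_denoise(
    stack: FrameStack, params: PhotometryParams | None = None
) -> tuple[FrameStack, np.ndarray]:
    """Predict each interior frame from its temporal neighborhood.

    Each pixel of frame t is replaced by the value predicted at t by a
    local linear regression over the ``denoise_half_window`` frames before
    and after t, excluding t itself. With a symmetric window the
    regression prediction at the center reduces to the neighborhood mean,
    so the operation preserves slow signal while averaging down
    uncorrelated noise by a factor of 2 * half_window.

    Border frames (within half_window of either end) are returned
    unmodified; the second return value flags the frames that were
    denoised.
    """
    params = params or PhotometryParams()
    hw = params.denoise_half_window
    T = stack.n_frames
    if T <= 2 * hw:
        raise ValueError(f"stack too short for half window {hw}: T={T}")
    # symmetric window excluding the center: prediction = neighborhood mean
    kernel = np.ones(2 * hw + 1)
    kernel[hw] = 0.0
    kernel /= kernel.sum()
    smoothed = ndimage.convolve1d(stack.data, kernel, axis=0, mode="nearest")
    out = stack.data.copy()
    out[hw : T - hw] = smoothed[hw : T - hw]
    denoised_mask = np.zeros(T, dtype=bool)
    denoised_mask[hw : T - hw] = True
    return stack.copy_with(out), denoised_mask
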