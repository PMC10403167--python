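"""Grayscale conversion, PSNR-guided smoothing, and unsharp sharpening.

A colour scan is first reduced to grayscale by the weighted sum

    g = 0.2989 R + 0.5878 G + 0.1140 B

(the weights sum to 1.0007; the result is clipped to [0, 255] rather than
renormalised).  The grayscale page is then smoothed by one of three window
filters — an adaptive Wiener filter, a median filter, or a low-pass (mean)
filter, all over a square mask (default 7×7) — and sharpened by an unsharp
mask with unit DC gain.  Which smoother to use is decided per page: each
candidate is run through smoothing + sharpening and the one whose output has
the highest PSNR against the grayscale input wins.

All window filters use mirror-reflected borders so page margins do not grow
dark halos that would later masquerade as edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import InvalidInputError, InvalidParameterError, PageImage

GRAY_WEIGHTS = (0.2989, 0.5878, 0.1140)

#: Laplacian-subtraction sharpening kernel; row sums to 1 (unit DC gain).
UNSHARP_KERNEL = np.array(
    [[0.0, -1.0, 0.0], [-1.0, 5.0, -1.0], [0.0, -1.0, 0.0]]
)

SMOOTHERS = ("wiener", "median", "lowpass")


@dataclass(frozen=True)
class QualityMetrics:
    """MSE (squared intensity units) and PSNR (dB) at a given peak value."""

    mse: float
    psnr: float  # math.inf when mse == 0
    peak: float = 255.0

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.psnr)


def to_grayscale(img: PageImage) -> PageImage:
    """Convert a 3-channel page to grayscale; gray input passes through."""
    if img.is_gray:
        return PageImage(img.pixels, stage="gray")
    r, g, b = (img.pixels[:, :, i] for i in range(3))
    wr, wg, wb = GRAY_WEIGHTS
    gray = wr * r + wg * g + wb * b
    return PageImage(np.clip(gray, 0.0, 255.0), stage="gray")


def _wiener(arr: np.ndarray, size: int) -> np.ndarray:
    # Local adaptive minimum-MSE filter (Lee form): the local mean plus the
    # noise-discounted residual; the noise floor is the mean local variance.
    local_mean = ndimage.uniform_filter(arr, size, mode="reflect")
    local_sqr = ndimage.uniform_filter(arr * arr, size, mode="reflect")
    local_var = np.maximum(local_sqr - local_mean**2, 0.0)
    noise = local_var.mean()
    denom = np.maximum(local_var, noise)
    if noise == 0.0:
        return local_mean + (arr - local_mean)
    gain = np.maximum(local_var - noise, 0.0) / denom
    return local_mean + gain * (arr - local_mean)


def smooth(img: PageImage, method: str = "wiener", mask_size: int = 7) -> PageImage:
    """Smooth a grayscale page with one of the three window filters."""
    if not img.is_gray:
        raise InvalidInputError("smooth expects a grayscale image")
    if mask_size % 2 == 0 or mask_size < 3:
        raise InvalidParameterError(f"mask_size must be odd and >= 3, got {mask_size}")
    if method not in SMOOTHERS:
        raise InvalidParameterError(f"unknown smoother {method!r}")
    arr = img.pixels
    if method == "wiener":
        out = _wiener(arr, mask_size)
    elif method == "median":
        out = ndimage.median_filter(arr, size=mask_size, mode="reflect")
    else:  # lowpass
        out = ndimage.uniform_filter(arr, size=mask_size, mode="reflect")
    return img.with_pixels(out, stage="smoothed")


def unsharp(img: PageImage, kernel: np.ndarray | None = None) -> PageImage:
    """Sharpen with a 3×3 unit-DC-gain kernel (constants map to themselves)."""
    if not img.is_gray:
        raise InvalidInputError("unsharp expects a grayscale image")
    k = UNSHARP_KERNEL if kernel is None else np.asarray(kernel, dtype=np.float64)
    out = ndimage.convolve(img.pixels, k, mode="reflect")
    return img.with_pixels(out, stage="enhanced")


def psnr(reference: PageImage, test: PageImage, peak: float = 255.0) -> QualityMetrics:
    """PSNR = 10 log10(peak² / MSE); identical images report infinite PSNR."""
    if reference.pixels.shape != test.pixels.shape:
        raise InvalidInputError("psnr requires equal image dimensions")
    if peak <= 0:
        raise InvalidParameterError("peak must be positive")
    diff = reference.pixels - test.pixels
    mse = float(np.mean(diff * diff))
    if mse == 0.0:
        return QualityMetrics(mse=0.0, psnr=math.inf, peak=peak)
    return QualityMetrics(mse=mse, psnr=10.0 * math.log10(peak * peak / mse), peak=peak)


def select_smoother(
    img: PageImage,
    methods: tuple[str, ...] = SMOOTHERS,
    mask_size: int = 7,
    peak: float = 255.0,
) -> tuple[str, PageImage]:
    """Run every candidate smoother + unsharp and keep the highest-PSNR one.

    PSNR is measured between the grayscale input and the sharpened output.
    Ties (including several infinite PSNRs) resolve by the fixed order
    wiener > median > lowpass.
    """
    if len(methods) == 0:
        raise InvalidParameterError("need at least one smoothing method")
    gray = to_grayscale(img)
    best: tuple[float, int, str, PageImage] | None = None
    order = {m: i for i, m in enumerate(SMOOTHERS)}
    for m in methods:
        enhanced = unsharp(smooth(gray, m, mask_size))
        q = psnr(gray, enhanced, peak=peak)
        key = (q.psnr, -order.get(m, len(order)))
        if best is None or key > (best[0], best[1]):
            best = (key[0], key[1], m, enhanced)
    assert best is not None
    return best[2], best[3]
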