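"""Undecimated à-trous wavelet decomposition and edge maps.

The à-trous ("with holes") algorithm smooths the image repeatedly with a
B3 cubic-spline low-pass kernel whose taps are dilated by zero insertion at
each level; no subsampling takes place, so every plane keeps the input's
size.  Detail planes are differences of consecutive approximations,

    A_0 = image,   A_j = A_{j-1} * K_j,   D_j = A_{j-1} - A_j,

which makes reconstruction the plain sum A_N + Σ D_j.  Edges at a chosen
scale are where the modulus of that scale's detail plane is large; the
binarisation threshold is k times a robust (median-based) estimate of the
detail noise level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import InvalidInputError, InvalidParameterError, PageImage


def b3_filter() -> np.ndarray:
    """The 5-tap B3 cubic-spline low-pass filter (1, 4, 6, 4, 1) / 16."""
    return np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def b3_kernel2d() -> np.ndarray:
    """Separable 5×5 low-pass kernel: outer product of the B3 filter."""
    f = b3_filter()
    return np.outer(f, f)


def _dilated_taps(level: int) -> np.ndarray:
    """B3 taps with 2^(level-1) - 1 zeros inserted between coefficients."""
    step = 2 ** (level - 1)
    taps = np.zeros(4 * step + 1)
    taps[::step] = b3_filter()
    return taps


def support(level: int) -> int:
    """Width of the dilated kernel at a level (4·2^(j−1) + 1 pixels)."""
    return 4 * 2 ** (level - 1) + 1


@dataclass
class WaveletDecomposition:
    """Approximation plane plus one same-size detail plane per level."""

    approximation: np.ndarray
    details: list[np.ndarray]

    @property
    def levels(self) -> int:
        return len(self.details)

    def __post_init__(self) -> None:
        shape = self.approximation.shape
        if any(d.shape != shape for d in self.details):
            raise InvalidInputError("all wavelet planes must share one shape")


@dataclass
class EdgeMap:
    """|detail| magnitudes at one scale with a thresholded binary map."""

    strength: np.ndarray
    binary: np.ndarray
    scale: int
    threshold: float


def atrous_decompose(img: PageImage | np.ndarray, levels: int = 3) -> WaveletDecomposition:
    """Decompose into ``levels`` detail planes plus a final approximation.

    Borders are mirror-extended; the image must be at least as large as the
    dilated kernel support at the deepest level.
    """
    arr = img.pixels if isinstance(img, PageImage) else np.asarray(img, dtype=np.float64)
    if levels < 1:
        raise InvalidParameterError("levels must be >= 1")
    min_dim = min(arr.shape)
    if support(levels) > min_dim:
        feasible = 0
        while support(feasible + 1) <= min_dim:
            feasible += 1
        raise InvalidParameterError(
            f"image too small for {levels} levels; maximum feasible level is {feasible}"
        )
    approx = arr.astype(np.float64)
    details: list[np.ndarray] = []
    for j in range(1, levels + 1):
        taps = _dilated_taps(j)
        nxt = ndimage.convolve1d(approx, taps, axis=0, mode="reflect")
        nxt = ndimage.convolve1d(nxt, taps, axis=1, mode="reflect")
        details.append(approx - nxt)
        approx = nxt
    return WaveletDecomposition(approximation=approx, details=details)


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Sum of the approximation and every detail plane (exact inverse)."""
    return dec.approximation + np.sum(dec.details, axis=0)


def edge_map(dec: WaveletDecomposition, scale: int = 2, k: float = 3.0) -> EdgeMap:
    """Binary edge map from the detail plane at ``scale``.

    The threshold is k × (median |D| / 0.6745), a robust estimate of k
    standard deviations of the detail noise.  A zero threshold (featureless
    plane) yields an empty map rather than an all-true one.
    """
    if not (1 <= scale <= dec.levels):
        raise InvalidParameterError(
            f"scale must be in [1, {dec.levels}], got {scale}"
        )
    strength = np.abs(dec.details[scale - 1])
    threshold = float(k * np.median(strength) / 0.6745)
    if threshold > 0.0:
        binary = strength >= threshold
    else:
        binary = strength > 0.0
    return EdgeMap(strength=strength, binary=binary, scale=scale, threshold=threshold)
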