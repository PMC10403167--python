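"""Page image container and raster I/O.

A scanned page travels through the pipeline as a :class:`PageImage`: a 2-D
float array of intensities in [0, 255] together with a ``stage`` tag that
records how far along the enhancement chain it is (raw RGB, grayscale,
smoothed, enhanced).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

STAGES = ("raw_rgb", "gray", "smoothed", "enhanced")


class InvalidInputError(ValueError):
    """Raised when an image or argument violates an operation's contract."""


class InvalidParameterError(ValueError):
    """Raised when a configuration parameter is out of its allowed range."""


@dataclass
class PageImage:
    """A page raster: ``pixels`` is (P, Q) gray or (P, Q, 3) RGB, float64."""

    pixels: np.ndarray
    stage: str = "gray"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            if self.stage == "raw_rgb":
                raise InvalidInputError("raw_rgb stage requires 3 channels")
        elif self.pixels.ndim == 3 and self.pixels.shape[2] == 3:
            self.stage = "raw_rgb"
        else:
            raise InvalidInputError(
                f"expected (P,Q) or (P,Q,3) pixels, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise InvalidInputError("empty image")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("non-finite intensities")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise InvalidInputError("intensities must lie in [0, 255]")
        if self.stage not in STAGES:
            raise InvalidParameterError(f"unknown stage {self.stage!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2

    def with_pixels(self, pixels: np.ndarray, stage: str) -> "PageImage":
        return PageImage(np.clip(pixels, 0.0, 255.0), stage=stage)


def read_page(path: str | Path) -> PageImage:
    """Read a PNG/TIFF/PGM page as a :class:`PageImage`.

    8-bit grayscale becomes stage ``gray``; 24-bit RGB (or RGBA, alpha
    dropped) becomes stage ``raw_rgb``.
    """
    arr = iio.imread(Path(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr.astype(np.float64), 0, 255)
    stage = "gray" if arr.ndim == 2 else "raw_rgb"
    return PageImage(arr.astype(np.float64), stage=stage)


def write_page(path: str | Path, img: PageImage | np.ndarray) -> None:
    """Write a gray or RGB image as 8-bit PNG/TIFF/PGM (by extension)."""
    arr = img.pixels if isinstance(img, PageImage) else np.asarray(img)
    iio.imwrite(Path(path), np.clip(np.round(arr), 0, 255).astype(np.uint8))
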