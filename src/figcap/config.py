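"""Single-file JSON configuration for every pipeline stage."""

from __future__ import annotations

import copy
import json
from pathlib import Path

from .image import InvalidParameterError

DEFAULTS: dict = {
    "smoothing": {"mask_size": 7, "methods": ["wiener", "median", "lowpass"]},
    "unsharp": {"kernel": [[0, -1, 0], [-1, 5, -1], [0, -1, 0]]},
    "psnr": {"peak": 255.0},
    "wavelet": {"levels": 3, "scale": 2, "k": 3.0},
    "regions": {
        "mode": "cc",  # cc: components of the binary edge map; mser: on grayscale
        "expand_px": 5,
        "min_box_area": 7000,
        "min_area_mode": "box",  # box: w*h of the merged box; pixels: region pixel count
        "min_cc_pixels": 25,
        "mser": {"delta": 5, "min_area": 30, "max_area": None, "max_variation": 0.5},
    },
    "textrec": {
        "glyph_size": 32,
        "reject_below": 0.5,
        "text_threshold_pct": 20.0,
        "glyph_min_px": 3,
        "glyph_max_px": 80,
    },
    "layout": {
        "h_overlap_frac": 0.3,
        "v_overlap_frac": 0.5,
        "gap_factor": 1.5,
        "word_gap_factor": 1.5,
        "segment_gap_factor": 2.5,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in out:
            raise InvalidParameterError(f"unknown config key {key!r}")
        if isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


class Config:
    """Pipeline configuration with dotted-path access (``cfg["wavelet.k"]``)."""

    def __init__(self, overrides: dict | None = None) -> None:
        self._data = _merge(DEFAULTS, overrides or {})

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        return cls(json.loads(Path(path).read_text()))

    def __getitem__(self, dotted: str):
        node = self._data
        for part in dotted.split("."):
            node = node[part]
        return node

    def to_dict(self) -> dict:
        return copy.deepcopy(self._data)
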