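"""Brute-force MSER oracle: explicit thresholding at all 256 levels.

Independent of the union-find sweep in figcap.regions: this version labels
every thresholded image directly and tracks component sizes per seed pixel.
Shares only the definition of the statistic, not any code path.
"""

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=bool)


def _one_polarity(values, delta, min_area, max_area, max_variation, polarity):
    h, w = values.shape
    n = h * w
    flat = values.ravel()
    order = np.lexsort((np.arange(n), flat))
    rank_of = np.empty(n, dtype=np.int64)
    rank_of[order] = np.arange(n)

    labs = []
    sizes = []
    seeds_per_level = {}  # t -> {seed: size}
    for t in range(256):
        lab, _ = ndimage.label(values <= t, structure=_EIGHT)
        labf = lab.ravel()
        labs.append(labf)
        sizes.append(np.bincount(labf))
        # first occurrence in rank order = minimum-rank member per component
        ranked = labf[order]
        comp_ids, first = np.unique(ranked, return_index=True)
        level = {}
        for cid, fi in zip(comp_ids, first):
            if cid == 0:
                continue
            level[int(order[fi])] = int(sizes[t][cid])
        seeds_per_level[t] = level

    canon = {}  # seed -> {t: size}
    for t, level in seeds_per_level.items():
        for s, sz in level.items():
            canon.setdefault(s, {})[t] = sz

    def area_at(s, t):
        if t < flat[s]:
            return 0
        return int(sizes[t][labs[t][s]])

    out = set()
    for s, levels in canon.items():
        birth, death = min(levels), max(levels)
        lo, hi = max(birth, delta), min(death, 255 - delta)
        if lo > hi:
            continue
        qs = [
            (area_at(s, t + delta) - area_at(s, t - delta)) / area_at(s, t)
            for t in range(lo, hi + 1)
        ]
        for i, q in enumerate(qs):
            left = qs[i - 1] if i > 0 else np.inf
            right = qs[i + 1] if i + 1 < len(qs) else np.inf
            if q <= left and q <= right and q <= max_variation:
                t = lo + i
                a = area_at(s, t)
                if min_area <= a <= max_area and a < n:
                    members = np.nonzero(labs[t] == labs[t][s])[0]
                    out.add((polarity, frozenset(members.tolist())))
    return out


def mser_oracle(img, delta=5, min_area=30, max_area=None, max_variation=0.5):
    values = np.clip(np.round(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.int64)
    if max_area is None:
        max_area = int(0.9 * values.size)
    dark = _one_polarity(values, delta, min_area, max_area, max_variation, "dark")
    bright = _one_polarity(255 - values, delta, min_area, max_area, max_variation, "bright")
    return dark | bright


def region_set(regions, width):
    """Canonical form of figcap Region output for comparison."""
    return {
        (r.polarity, frozenset((r.pixels[:, 0] * width + r.pixels[:, 1]).tolist()))
        for r in regions
    }
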