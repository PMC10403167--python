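"""Connected components, MSERs, and bounding-box post-processing.

Candidate layout blocks come from the edge image: maximal 8-connected sets
of edge pixels (or, alternatively, maximally stable extremal regions of a
graded image).  Their tight bounding boxes are expanded by a few pixels so
that boxes of neighbouring glyphs and figure fragments overlap, overlapping
boxes are merged to a fixpoint, and boxes smaller than an area threshold
(7,000 px² by default, per the source method's operating point) are
discarded.

Boxes are 0-based, half-open ``[x0, x0+w) × [y0, y0+h)`` with x rightward
and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _graph_cc

from .image import InvalidParameterError, PageImage
from .wavelet import EdgeMap

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True, order=True)
class BBox:
    """Half-open pixel rectangle. Sort order is (y0, x0, w, h)."""

    y0: int
    x0: int
    h: int
    w: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise InvalidParameterError("BBox needs w >= 1 and h >= 1")

    @classmethod
    def from_xywh(cls, x0: int, y0: int, w: int, h: int) -> "BBox":
        return cls(y0=y0, x0=x0, h=h, w=w)

    @property
    def x1(self) -> int:  # exclusive
        return self.x0 + self.w

    @property
    def y1(self) -> int:  # exclusive
        return self.y0 + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    def intersects(self, other: "BBox") -> bool:
        """True for positive-area overlap or a shared edge (touching)."""
        return (
            self.x0 <= other.x1
            and other.x0 <= self.x1
            and self.y0 <= other.y1
            and other.y0 <= self.y1
        )

    def union(self, other: "BBox") -> "BBox":
        x0 = min(self.x0, other.x0)
        y0 = min(self.y0, other.y0)
        return BBox(
            y0=y0,
            x0=x0,
            h=max(self.y1, other.y1) - y0,
            w=max(self.x1, other.x1) - x0,
        )

    def iou(self, other: "BBox") -> float:
        ix = min(self.x1, other.x1) - max(self.x0, other.x0)
        iy = min(self.y1, other.y1) - max(self.y0, other.y0)
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        return inter / (self.area + other.area - inter)

    def expand(self, amount: int, page_h: int, page_w: int) -> "BBox":
        x0 = max(self.x0 - amount, 0)
        y0 = max(self.y0 - amount, 0)
        x1 = min(self.x1 + amount, page_w)
        y1 = min(self.y1 + amount, page_h)
        return BBox(y0=y0, x0=x0, h=y1 - y0, w=x1 - x0)

    def to_dict(self) -> dict:
        return {"x0": self.x0, "y0": self.y0, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "BBox":
        return cls(y0=int(d["y0"]), x0=int(d["x0"]), h=int(d["h"]), w=int(d["w"]))


@dataclass
class Region:
    """An 8-connected pixel set with its tight box.

    ``pixels`` is an (n, 2) array of (y, x) coordinates.  MSER output also
    carries the polarity, the extraction level, and the stability score.
    """

    pixels: np.ndarray
    bbox: BBox
    polarity: str = "dark"
    stability: float = 0.0
    level: int = 0

    @property
    def size(self) -> int:
        return len(self.pixels)


def _tight_bbox(ys: np.ndarray, xs: np.ndarray) -> BBox:
    y0, y1 = int(ys.min()), int(ys.max())
    x0, x1 = int(xs.min()), int(xs.max())
    return BBox(y0=y0, x0=x0, h=y1 - y0 + 1, w=x1 - x0 + 1)


def connected_components(binary: EdgeMap | np.ndarray, min_pixels: int = 1) -> list[Region]:
    """Maximal 8-connected true-pixel sets, ordered by (y0, x0).

    ``min_pixels`` drops components below a pixel count before any box
    processing; isolated noise responses otherwise survive into the
    expansion stage.
    """
    grid = binary.binary if isinstance(binary, EdgeMap) else np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(grid, structure=_EIGHT)
    regions: list[Region] = []
    if n == 0:
        return regions
    objects = ndimage.find_objects(labels)
    for i, sl in enumerate(objects, start=1):
        ys, xs = np.nonzero(labels[sl] == i)
        if len(ys) < min_pixels:
            continue
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        regions.append(
            Region(pixels=np.column_stack([ys, xs]), bbox=_tight_bbox(ys, xs))
        )
    regions.sort(key=lambda r: (r.bbox.y0, r.bbox.x0))
    return regions


def expand_boxes(boxes: list[BBox], amount: int, page_h: int, page_w: int) -> list[BBox]:
    """Grow each box by ``amount`` px on all four sides, clipped to the page."""
    if amount < 0:
        raise InvalidParameterError("expansion amount must be >= 0")
    return [b.expand(amount, page_h, page_w) for b in boxes]


def merge_overlapping(boxes: list[BBox]) -> list[BBox]:
    """Union overlapping (or edge-touching) boxes until none overlap.

    Implemented by repeatedly taking connected components of the overlap
    graph and replacing each group by its union box; unions can create new
    overlaps, so the pass iterates to a fixpoint.  The result is ordered by
    (y0, x0) and is idempotent.
    """
    current = list(boxes)
    while True:
        n = len(current)
        if n <= 1:
            break
        x0 = np.array([b.x0 for b in current])
        x1 = np.array([b.x1 for b in current])
        y0 = np.array([b.y0 for b in current])
        y1 = np.array([b.y1 for b in current])
        ox = (x0[:, None] <= x1[None, :]) & (x0[None, :] <= x1[:, None])
        oy = (y0[:, None] <= y1[None, :]) & (y0[None, :] <= y1[:, None])
        adj = ox & oy
        n_comp, labels = _graph_cc(coo_matrix(adj), directed=False)
        if n_comp == n:
            break
        merged: list[BBox] = []
        for c in range(n_comp):
            idx = np.nonzero(labels == c)[0]
            gx0, gy0 = int(x0[idx].min()), int(y0[idx].min())
            gx1, gy1 = int(x1[idx].max()), int(y1[idx].max())
            merged.append(BBox(y0=gy0, x0=gx0, h=gy1 - gy0, w=gx1 - gx0))
        current = merged
    return sorted(current)


def filter_small(boxes: list[BBox], min_area: int = 7000) -> list[BBox]:
    """Keep boxes whose area w·h is at least ``min_area`` px²."""
    if min_area < 0:
        raise InvalidParameterError("min_area must be >= 0")
    return [b for b in boxes if b.area >= min_area]


# ---------------------------------------------------------------------------
# Maximally stable extremal regions
# ---------------------------------------------------------------------------


class _UnionFind:
    __slots__ = ("parent", "size", "seed")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n
        self.seed = list(range(n))  # index of the set's seed pixel

    def find(self, a: int) -> int:
        p = self.parent
        root = a
        while p[root] != root:
            root = p[root]
        while p[a] != root:
            p[a], a = root, p[a]
        return root

    def union(self, a: int, b: int, seed_rank: list[int]) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        # attach the set with the larger (younger) seed under the other
        if seed_rank[self.seed[ra]] > seed_rank[self.seed[rb]]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return ra


def _mser_one_polarity(
    values: np.ndarray,
    delta: int,
    min_area: int,
    max_area: int,
    max_variation: float,
    polarity: str,
) -> list[Region]:
    """Single-polarity MSER by a union-find sweep over intensity levels.

    A branch of the component tree is identified by its seed — the pixel
    that is lexicographically smallest by (intensity, y, x) within the
    component.  After all pixels of a level are merged in, each live root
    records its size for that level; a branch whose seed is displaced by a
    merge dies and thereafter inherits the winner's sizes.  Stability at
    level t is (A(t+Δ) − A(t−Δ)) / A(t) along the branch (A := 0 before
    birth); regions are taken at local minima of the stability with value
    ≤ max_variation and area within [min_area, max_area].  The full-image
    component has no outer boundary and is never extremal.
    """
    h, w = values.shape
    n = h * w
    flat = values.ravel()
    order = np.lexsort((np.arange(n), flat))  # by (value, linear index)
    seed_rank = np.empty(n, dtype=np.int64)
    seed_rank[order] = np.arange(n)
    seed_rank_l = seed_rank.tolist()

    uf = _UnionFind(n)
    added = np.zeros(n, dtype=bool)
    # per-seed histories
    birth: dict[int, int] = {}
    death: dict[int, int] = {}
    sizes: dict[int, list[int]] = {}
    merged_into: dict[int, int] = {}

    neigh_off = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

    pos = 0
    live: set[int] = set()  # seeds canonical at the previous level
    for t in range(256):
        while pos < n and flat[order[pos]] == t:
            idx = int(order[pos])
            added[idx] = True
            y, x = divmod(idx, w)
            for dy, dx in neigh_off:
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w:
                    nidx = ny * w + nx
                    if added[nidx]:
                        uf.union(idx, nidx, seed_rank_l)
            pos += 1
        # end-of-level snapshot
        new_live: set[int] = set()
        snapshot_roots: set[int] = set()
        for s in live:
            snapshot_roots.add(uf.find(s))
        # roots of pixels added this level may be brand-new components
        # (collect roots via the seeds of current sets containing this level's pixels)
        start = pos - 1
        while start >= 0 and flat[order[start]] == t:
            snapshot_roots.add(uf.find(int(order[start])))
            start -= 1
        for root in snapshot_roots:
            s = uf.seed[root]
            if s not in birth:
                birth[s] = t
                sizes[s] = []
            sizes[s].append(uf.size[root])
            new_live.add(s)
        for s in live:
            if s not in new_live:
                death[s] = t - 1
                merged_into[s] = uf.seed[uf.find(s)]
        live = new_live
    for s in live:
        death[s] = 255

    def area_at(s: int, t: int) -> int:
        if t < birth[s]:
            return 0
        while t > death[s]:
            s = merged_into[s]
        return sizes[s][t - birth[s]]

    picks: list[tuple[int, int, float]] = []  # (seed, level, q)
    for s, b in birth.items():
        lo = max(b, delta)
        hi = min(death[s], 255 - delta)
        if lo > hi:
            continue
        qs = []
        for t in range(lo, hi + 1):
            a_t = area_at(s, t)
            qs.append((area_at(s, t + delta) - area_at(s, t - delta)) / a_t)
        for i, q in enumerate(qs):
            left = qs[i - 1] if i > 0 else np.inf
            right = qs[i + 1] if i + 1 < len(qs) else np.inf
            if q <= left and q <= right and q <= max_variation:
                t = lo + i
                a = area_at(s, t)
                if min_area <= a <= max_area and a < n:
                    picks.append((s, t, q))

    # extract pixel sets, one labelling per needed level
    regions: list[Region] = []
    seen: set[tuple] = set()
    by_level: dict[int, list[tuple[int, float]]] = {}
    for s, t, q in picks:
        by_level.setdefault(t, []).append((s, q))
    for t in sorted(by_level):
        labels, _ = ndimage.label(values <= t, structure=_EIGHT)
        lab_flat = labels.ravel()
        for s, q in by_level[t]:
            comp = lab_flat == lab_flat[s]
            ys, xs = np.nonzero(comp.reshape(h, w))
            key = (ys.tobytes(), xs.tobytes())
            if key in seen:
                continue
            seen.add(key)
            regions.append(
                Region(
                    pixels=np.column_stack([ys, xs]),
                    bbox=_tight_bbox(ys, xs),
                    polarity=polarity,
                    stability=float(q),
                    level=t,
                )
            )
    regions.sort(key=lambda r: (r.bbox.y0, r.bbox.x0, r.level, r.size))
    return regions


def mser_detect(
    gray: PageImage | np.ndarray,
    delta: int = 5,
    min_area: int = 30,
    max_area: int | None = None,
    max_variation: float = 0.5,
) -> list[Region]:
    """Maximally stable extremal regions of both polarities.

    Dark regions are components of ``I <= t`` sweeps; bright regions come
    from the same sweep on the inverted image.  ``max_area`` defaults to
    0.9 × the page area.
    """
    arr = gray.pixels if isinstance(gray, PageImage) else np.asarray(gray, dtype=np.float64)
    values = np.clip(np.round(arr), 0, 255).astype(np.int64)
    if delta < 1:
        raise InvalidParameterError("delta must be >= 1")
    if max_area is None:
        max_area = int(0.9 * values.size)
    if min_area > max_area:
        raise InvalidParameterError("min_area must not exceed max_area")
    dark = _mser_one_polarity(values, delta, min_area, max_area, max_variation, "dark")
    bright = _mser_one_polarity(
        255 - values, delta, min_area, max_area, max_variation, "bright"
    )
    return dark + bright
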