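"""Seeded synthetic scanned pages with exact ground truth.

The generator emulates single- and double-column book pages: body-text
paragraphs rendered from the package's bitmap font, zero or more figure
regions (smoothed-noise "photo" fill, outlined shape panels, or a framed
gradient), and one caption per figure that starts with "Figure N." and ends
with a period, placed below, above, or beside its figure.  Additive
Gaussian noise is applied last.  Because every ink pixel is placed by the
generator, the ground-truth boxes are exact, which makes every pipeline
stage testable without any external scans.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import font as _font
from .image import InvalidInputError, PageImage, write_page
from .regions import BBox

DIFFICULTIES = ("simple", "multi_panel", "two_column")


@dataclass
class FigureSpec:
    bbox: BBox
    style: str = "noise"  # noise | shapes | gradient


@dataclass
class CaptionSpec:
    text: str
    placement: str = "below"  # below | above | side


@dataclass
class PageSpec:
    """Declarative description of one synthetic page."""

    height: int = 1100
    width: int = 850
    columns: int = 1
    figures: list[FigureSpec] = field(default_factory=list)
    captions: list[CaptionSpec] = field(default_factory=list)
    n_paragraphs: int = 3
    noise_sigma: float = 5.0
    seed: int = 0
    font_scale: int = 3
    margin: int = 60
    line_gap: int = 6
    element_gap: int = 34
    gutter: int = 44


@dataclass
class GroundTruth:
    """Per-page truth: element boxes, caption strings, pair assignments."""

    page: str
    figures: list[BBox]
    captions: list[BBox]
    caption_texts: list[str]
    relations: list[str]

    @property
    def pairs(self) -> list[BBox]:
        return [f.union(c) for f, c in zip(self.figures, self.captions)]

    def to_dict(self) -> dict:
        return {
            "page": self.page,
            "figures": [b.to_dict() for b in self.figures],
            "captions": [b.to_dict() for b in self.captions],
            "pairs": [
                {
                    "figure_bbox": f.to_dict(),
                    "caption_bbox": c.to_dict(),
                    "merged_bbox": f.union(c).to_dict(),
                    "relation": r,
                    "caption_text": t,
                }
                for f, c, r, t in zip(
                    self.figures, self.captions, self.relations, self.caption_texts
                )
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            page=d["page"],
            figures=[BBox.from_dict(b) for b in d["figures"]],
            captions=[BBox.from_dict(b) for b in d["captions"]],
            caption_texts=[p["caption_text"] for p in d["pairs"]],
            relations=[p["relation"] for p in d["pairs"]],
        )


# ---------------------------------------------------------------------------
# text rendering
# ---------------------------------------------------------------------------


def _draw_text_line(canvas: np.ndarray, x: int, y: int, text: str, scale: int) -> BBox | None:
    """Draw one line of text with its cell top-left at (x, y); tight ink box."""
    cw, ch = _font.CELL_W * scale, _font.CELL_H * scale
    gap = scale  # one font column between cells
    space = 3 * scale
    bounds = None
    cx = x
    for char in text:
        if char == " ":
            cx += space + gap
            continue
        bm = _font.glyph_bitmap(char, scale)
        ys, xs = np.nonzero(bm)
        canvas[y + ys, cx + xs] = 0.0
        b = BBox(
            y0=y + int(ys.min()),
            x0=cx + int(xs.min()),
            h=int(ys.max() - ys.min()) + 1,
            w=int(xs.max() - xs.min()) + 1,
        )
        bounds = b if bounds is None else bounds.union(b)
        cx += cw + gap
    return bounds


def _line_width(text: str, scale: int) -> int:
    cw, gap, space = _font.CELL_W * scale, scale, 3 * scale
    width = 0
    for char in text:
        width += (space + gap) if char == " " else (cw + gap)
    return width


def _wrap(text: str, max_width: int, scale: int) -> list[str]:
    words = text.split(" ")
    lines: list[str] = []
    cur = ""
    for word in words:
        trial = word if not cur else cur + " " + word
        if cur and _line_width(trial, scale) > max_width:
            lines.append(cur)
            cur = word
        else:
            cur = trial
    if cur:
        lines.append(cur)
    return lines


def _draw_paragraph(
    canvas: np.ndarray, x: int, y: int, lines: list[str], scale: int, line_gap: int
) -> BBox | None:
    ch = _font.CELL_H * scale
    bounds = None
    for i, line in enumerate(lines):
        b = _draw_text_line(canvas, x, y + i * (ch + line_gap), line, scale)
        if b is not None:
            bounds = b if bounds is None else bounds.union(b)
    return bounds


def _random_word(rng: np.random.Generator, lo: int = 3, hi: int = 8) -> str:
    n = int(rng.integers(lo, hi + 1))
    letters = "abcdefghijklmnopqrstuvwxyz"
    return "".join(letters[int(i)] for i in rng.integers(0, 26, size=n))


# ---------------------------------------------------------------------------
# figure content styles
# ---------------------------------------------------------------------------


def _fill_figure(canvas: np.ndarray, box: BBox, style: str, rng: np.random.Generator) -> None:
    h, w = box.h, box.w
    view = canvas[box.y0 : box.y1, box.x0 : box.x1]
    if style == "noise":
        # photo-like fill: smoothed noise, guaranteed non-background
        from scipy import ndimage

        field_ = rng.normal(0, 1, size=(h, w))
        field_ = ndimage.uniform_filter(field_, 5)
        lo, hi = field_.min(), field_.max()
        view[:, :] = 20 + 180 * (field_ - lo) / max(hi - lo, 1e-9)
    elif style == "gradient":
        ramp = np.linspace(40, 200, w)[None, :]
        view[:, :] = np.broadcast_to(ramp, (h, w))
        view[:2, :] = 0.0
        view[-2:, :] = 0.0
        view[:, :2] = 0.0
        view[:, -2:] = 0.0
    elif style == "shapes":
        view[:, :] = 245.0
        view[:2, :] = 0.0
        view[-2:, :] = 0.0
        view[:, :2] = 0.0
        view[:, -2:] = 0.0
        n_shapes = int(rng.integers(3, 7))
        for _ in range(n_shapes):
            sw = int(rng.integers(w // 8, max(w // 3, w // 8 + 1)))
            sh = int(rng.integers(h // 8, max(h // 3, h // 8 + 1)))
            sx = int(rng.integers(4, max(w - sw - 4, 5)))
            sy = int(rng.integers(4, max(h - sh - 4, 5)))
            shade = float(rng.uniform(0, 160))
            if rng.random() < 0.5:
                view[sy : sy + sh, sx : sx + sw] = shade
            else:  # outlined panel
                view[sy : sy + sh, sx : sx + 2] = shade
                view[sy : sy + sh, sx + sw - 2 : sx + sw] = shade
                view[sy : sy + 2, sx : sx + sw] = shade
                view[sy + sh - 2 : sy + sh, sx : sx + sw] = shade
    else:
        raise InvalidInputError(f"unknown figure style {style!r}")


# ---------------------------------------------------------------------------
# page rendering
# ---------------------------------------------------------------------------


def _caption_origin(
    fig: BBox, placement: str, spec: PageSpec, n_lines: int, width: int
) -> tuple[int, int]:
    ch = _font.CELL_H * spec.font_scale
    block_h = n_lines * ch + (n_lines - 1) * spec.line_gap
    if placement == "below":
        return fig.x0, fig.y1 + spec.element_gap
    if placement == "above":
        return fig.x0, fig.y0 - spec.element_gap - block_h
    if placement == "side":
        y = fig.y0 + max((fig.h - block_h) // 2, 0)
        return fig.x1 + spec.element_gap, y
    raise InvalidInputError(f"unknown caption placement {placement!r}")


def render_page(spec: PageSpec) -> tuple[PageImage, GroundTruth]:
    """Render a page deterministically for a fixed spec + seed."""
    if len(spec.figures) != len(spec.captions):
        raise InvalidInputError("need one caption spec per figure spec")
    rng = np.random.default_rng(spec.seed)
    canvas = np.full((spec.height, spec.width), 255.0)

    fig_boxes: list[BBox] = []
    cap_boxes: list[BBox] = []
    relations = {"below": "caption_below", "above": "caption_above", "side": "caption_side"}

    for fig, cap in zip(spec.figures, spec.captions):
        b = fig.bbox
        if b.x0 < 0 or b.y0 < 0 or b.x1 > spec.width or b.y1 > spec.height:
            raise InvalidInputError("figure box outside page")
        _fill_figure(canvas, b, fig.style, rng)
        fig_boxes.append(b)
        max_w = b.w if cap.placement in ("below", "above") else max(
            150, spec.width - spec.margin - (b.x1 + spec.element_gap)
        )
        lines = _wrap(cap.text, max_w, spec.font_scale)
        x, y = _caption_origin(b, cap.placement, spec, len(lines), max_w)
        tight = _draw_paragraph(canvas, x, y, lines, spec.font_scale, spec.line_gap)
        if tight is None:
            raise InvalidInputError("caption rendered no ink")
        cap_boxes.append(tight)

    occupied = [
        bx.expand(spec.element_gap - 1, spec.height, spec.width)
        for bx in fig_boxes + cap_boxes
    ]
    for i, a in enumerate(fig_boxes + cap_boxes):
        for j, b in enumerate(fig_boxes + cap_boxes):
            if i < j and a.intersects(b):
                raise InvalidInputError("figure/caption boxes overlap in the spec")

    # body paragraphs fill the free space of each column
    ch = _font.CELL_H * spec.font_scale
    col_w = (spec.width - 2 * spec.margin - (spec.columns - 1) * spec.gutter) // spec.columns
    placed = 0
    for col in range(spec.columns):
        cx0 = spec.margin + col * (col_w + spec.gutter)
        y = spec.margin
        while placed < spec.n_paragraphs * spec.columns and y < spec.height - spec.margin - ch:
            n_lines = int(rng.integers(2, 6))
            block_h = n_lines * (ch + spec.line_gap)
            block = BBox(y0=y, x0=cx0, h=block_h, w=col_w)
            clash = next((o for o in occupied if o.intersects(block)), None)
            if clash is not None:
                y = clash.y1 + 1
                continue
            if block.y1 > spec.height - spec.margin:
                break
            lines = []
            for _ in range(n_lines):
                words: list[str] = []
                while True:
                    word = _random_word(rng)
                    if _line_width(" ".join(words + [word]), spec.font_scale) > col_w:
                        break
                    words.append(word)
                lines.append(" ".join(words))
            _draw_paragraph(canvas, cx0, y, lines, spec.font_scale, spec.line_gap)
            placed += 1
            y += block_h + spec.element_gap

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)

    truth = GroundTruth(
        page="page",
        figures=fig_boxes,
        captions=cap_boxes,
        caption_texts=[c.text for c in spec.captions],
        relations=[relations[c.placement] for c in spec.captions],
    )
    return PageImage(canvas, stage="gray"), truth


# ---------------------------------------------------------------------------
# glyph training data
# ---------------------------------------------------------------------------


def render_glyph_dataset(
    alphabet: str = _font.ALPHABET_62,
    samples_per_class: int = 200,
    shift: int = 2,
    scale_jitter: float = 0.15,
    salt: float = 0.02,
    seed: int = 0,
    base_scale: int = 3,
) -> list[tuple[np.ndarray, str]]:
    """Jittered bitmap samples per class: ±shift px, ±scale_jitter, salt flips."""
    if samples_per_class < 1:
        raise InvalidInputError("samples_per_class must be >= 1")
    for c in alphabet:
        if not _font.has_glyph(c):
            raise InvalidInputError(f"alphabet symbol {c!r} has no glyph")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, str]] = []
    for c in alphabet:
        base = _font.glyph_bitmap(c, base_scale)
        h, w = base.shape
        for _ in range(samples_per_class):
            f = 1.0 + rng.uniform(-scale_jitter, scale_jitter)
            nh, nw = max(2, round(h * f)), max(2, round(w * f))
            ri = np.minimum((np.arange(nh) + 0.5) * h / nh, h - 1).astype(int)
            ci = np.minimum((np.arange(nw) + 0.5) * w / nw, w - 1).astype(int)
            g = base[np.ix_(ri, ci)]
            pad = shift + 1
            canvas = np.zeros((nh + 2 * pad, nw + 2 * pad), dtype=bool)
            dy = int(rng.integers(-shift, shift + 1))
            dx = int(rng.integers(-shift, shift + 1))
            canvas[pad + dy : pad + dy + nh, pad + dx : pad + dx + nw] = g
            if salt > 0:
                flips = rng.random(canvas.shape) < salt
                canvas = canvas ^ flips
            if not canvas.any():
                canvas[pad, pad] = True
            out.append((canvas, c))
    return out


# ---------------------------------------------------------------------------
# corpus presets
# ---------------------------------------------------------------------------


def _caption_text(rng: np.random.Generator, number: int, min_words: int = 4) -> str:
    n = int(rng.integers(min_words, min_words + 5))
    words = " ".join(_random_word(rng) for _ in range(n))
    return f"Figure {number}. {words}."


def _sample_spec(difficulty: str, seed: int, rng: np.random.Generator) -> PageSpec:
    spec = PageSpec(seed=seed)
    margin, gap = spec.margin, spec.element_gap
    cap_zone = 110  # caption allowance below/above a figure
    if difficulty == "simple":
        w = int(rng.integers(340, 490))
        h = int(rng.integers(230, 330))
        x = margin + int(rng.integers(0, spec.width - 2 * margin - w + 1))
        y = margin + int(rng.integers(30, 280))
        spec.figures = [FigureSpec(BBox(y0=y, x0=x, h=h, w=w), style=str(rng.choice(["noise", "shapes"])))]
        spec.captions = [CaptionSpec(_caption_text(rng, int(rng.integers(1, 20))))]
        spec.n_paragraphs = 3
    elif difficulty == "multi_panel":
        n_figs = int(rng.integers(1, 3))
        spec.figures, spec.captions = [], []
        slot_h = (spec.height - 2 * margin) // n_figs
        for i in range(n_figs):
            w = int(rng.integers(320, 460))
            h = int(rng.integers(200, min(290, slot_h - cap_zone - 2 * gap)))
            x = margin + int(rng.integers(0, spec.width - 2 * margin - w + 1))
            slot_y0 = margin + i * slot_h
            style = str(rng.choice(["shapes", "noise", "gradient"]))
            placement = "below"
            if rng.random() < 0.25:
                placement = "above"
            if placement == "above":
                y = slot_y0 + cap_zone + int(rng.integers(0, 30))
            else:
                y = slot_y0 + int(rng.integers(0, 30))
            spec.figures.append(FigureSpec(BBox(y0=y, x0=x, h=h, w=w), style=style))
            spec.captions.append(
                CaptionSpec(_caption_text(rng, int(rng.integers(1, 20))), placement=placement)
            )
        spec.n_paragraphs = 2
    elif difficulty == "two_column":
        spec.columns = 2
        col_w = (spec.width - 2 * margin - spec.gutter) // 2
        n_pairs = int(rng.integers(1, 3))
        cols = [0, 1] if n_pairs == 2 else [int(rng.integers(0, 2))]
        spec.figures, spec.captions = [], []
        for col in cols:
            cx0 = margin + col * (col_w + spec.gutter)
            w = int(rng.integers(240, col_w - 10))
            h = int(rng.integers(200, 300))
            x = cx0 + int(rng.integers(0, col_w - w + 1))
            y = margin + int(rng.integers(30, spec.height - 2 * margin - h - cap_zone - 60))
            spec.figures.append(
                FigureSpec(BBox(y0=y, x0=x, h=h, w=w), style=str(rng.choice(["noise", "shapes"])))
            )
            spec.captions.append(CaptionSpec(_caption_text(rng, int(rng.integers(1, 20)), min_words=2)))
        spec.n_paragraphs = 2
    else:
        raise InvalidInputError(f"unknown difficulty {difficulty!r}")
    return spec


def corpus(
    n_pages: int, difficulty: str = "simple", seed: int = 1
) -> list[tuple[PageImage, GroundTruth]]:
    """A deterministic list of rendered pages for one difficulty preset.

    ``difficulty="mixed"`` cycles through all three presets.
    """
    if n_pages < 1:
        raise InvalidInputError("n_pages must be >= 1")
    rng = np.random.default_rng(seed)
    pages = []
    for i in range(n_pages):
        diff = difficulty
        if difficulty == "mixed":
            diff = DIFFICULTIES[i % len(DIFFICULTIES)]
        page_seed = int(rng.integers(0, 2**31 - 1))
        spec = _sample_spec(diff, page_seed, rng)
        img, truth = render_page(spec)
        truth.page = f"page{i:03d}"
        pages.append((img, truth))
    return pages


def write_corpus(out_dir: str | Path, pages: list[tuple[PageImage, GroundTruth]]) -> None:
    """PNG page + ground-truth JSON per page, plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["page", "image", "truth", "n_pairs"])
        for img, truth in pages:
            png = f"{truth.page}.png"
            tj = f"{truth.page}_truth.json"
            write_page(out / png, img)
            with open(out / tj, "w") as tfh:
                json.dump(truth.to_dict(), tfh, indent=1)
            writer.writerow([truth.page, png, tj, len(truth.figures)])
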