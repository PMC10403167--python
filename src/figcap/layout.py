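"""Caption detection and figure–caption pairing.

Classified glyphs are grouped into text lines; a line whose string opens
with one of the caption header prefixes (Fig, FIG, Figure, FIGURE, with an
optional '.'/':' separator and a figure number) seeds a caption candidate.
The candidate grows downward line by line while the inter-line gap stays
within 1.5× the page's median line gap, and closes after a line that ends
with a period followed by a larger gap (or the end of the block/page).
Each closed caption is then associated with the nearest graphic box whose
geometry admits one of three relations — figure above the caption, figure
below it, or figure at its side — and the pair is exported as the minimal
box containing both.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image import PageImage, write_page
from .regions import BBox

HEADER_RE = re.compile(r"^(Figure|FIGURE|Fig|FIG)[.:]?\s*\S{0,3}\d")

RELATIONS = ("caption_below", "caption_above", "caption_side")


@dataclass
class ClassifiedGlyph:
    bbox: BBox
    char: str
    confidence: float


@dataclass
class TextLine:
    bbox: BBox
    glyphs: list[ClassifiedGlyph]
    text: str


@dataclass
class CaptionCandidate:
    header: str
    bbox: BBox
    lines: list[TextLine]
    closed: bool = False

    @property
    def text(self) -> str:
        return " ".join(ln.text for ln in self.lines)


@dataclass
class FigureCaptionPair:
    figure: BBox
    caption: BBox
    merged: BBox
    relation: str
    caption_text: str = ""
    page: str = ""


def group_lines(
    glyphs: list[ClassifiedGlyph],
    word_gap_factor: float = 1.5,
    segment_gap_factor: float = 2.5,
) -> list[TextLine]:
    """Group glyph boxes into lines; gaps wider than ``word_gap_factor`` ×
    the median glyph width become spaces in the string rendering.

    Two glyphs share a line when their boxes overlap vertically by at least
    half the smaller height.  A horizontal gap beyond ``segment_gap_factor``
    × the median glyph width splits the row into separate lines — that is
    what keeps text in adjacent columns of a two-column page apart.
    """
    if not glyphs:
        return []
    order = sorted(range(len(glyphs)), key=lambda i: (glyphs[i].bbox.y0, glyphs[i].bbox.x0))
    lines: list[list[int]] = []
    spans: list[tuple[int, int]] = []  # running (y0, y1) per line
    for i in order:
        b = glyphs[i].bbox
        attached = False
        for li in range(len(lines) - 1, -1, -1):
            y0, y1 = spans[li]
            overlap = min(y1, b.y1) - max(y0, b.y0)
            if overlap >= 0.5 * min(y1 - y0, b.h):
                lines[li].append(i)
                spans[li] = (min(y0, b.y0), max(y1, b.y1))
                attached = True
                break
        if not attached:
            lines.append([i])
            spans.append((b.y0, b.y1))
    widths = [g.bbox.w for g in glyphs]
    med_w = float(np.median(widths))
    out: list[TextLine] = []
    for members in lines:
        members.sort(key=lambda i: glyphs[i].bbox.x0)
        segments: list[list[int]] = [[members[0]]]
        for i in members[1:]:
            gap = glyphs[i].bbox.x0 - glyphs[segments[-1][-1]].bbox.x1
            if gap > segment_gap_factor * med_w:
                segments.append([i])
            else:
                segments[-1].append(i)
        for seg in segments:
            bbox = glyphs[seg[0]].bbox
            chars: list[str] = []
            prev_x1 = None
            for i in seg:
                g = glyphs[i]
                bbox = bbox.union(g.bbox)
                if prev_x1 is not None and g.bbox.x0 - prev_x1 > word_gap_factor * med_w:
                    chars.append(" ")
                chars.append(g.char)
                prev_x1 = g.bbox.x1
            out.append(TextLine(bbox=bbox, glyphs=[glyphs[i] for i in seg], text="".join(chars)))
    out.sort(key=lambda ln: (ln.bbox.y0, ln.bbox.x0))
    return out


def find_caption_headers(lines: list[TextLine]) -> list[CaptionCandidate]:
    """Open a candidate for every line that starts like a caption header."""
    found = []
    for ln in lines:
        m = HEADER_RE.match(ln.text)
        if m:
            found.append(CaptionCandidate(header=m.group(1), bbox=ln.bbox, lines=[ln]))
    return found


def median_line_gap(lines: list[TextLine]) -> float:
    """Median vertical gap between consecutive, horizontally aligned lines."""
    gaps = []
    ordered = sorted(lines, key=lambda ln: ln.bbox.y0)
    for a, b in zip(ordered, ordered[1:]):
        if a.bbox.x0 < b.bbox.x1 and b.bbox.x0 < a.bbox.x1:
            gap = b.bbox.y0 - a.bbox.y1
            if gap >= 0:
                gaps.append(gap)
    return float(np.median(gaps)) if gaps else 0.0


def grow_caption(
    cand: CaptionCandidate,
    lines: list[TextLine],
    median_gap: float,
    gap_factor: float = 1.5,
) -> CaptionCandidate:
    """Attach following lines until the period-plus-gap termination rule."""
    threshold = gap_factor * max(median_gap, 1.0)
    below = sorted(
        (
            ln
            for ln in lines
            if ln.bbox.y0 > cand.lines[-1].bbox.y0
            and ln.bbox.x0 < cand.bbox.x1
            and cand.bbox.x0 < ln.bbox.x1
        ),
        key=lambda ln: ln.bbox.y0,
    )
    for nxt in below:
        gap = nxt.bbox.y0 - cand.lines[-1].bbox.y1
        if gap > threshold:
            break  # paragraph-scale gap: the block ends here
        cand.lines.append(nxt)
        cand.bbox = cand.bbox.union(nxt.bbox)
    cand.closed = True
    return cand


def _relation(fig: BBox, cap: BBox, h_overlap_frac: float, v_overlap_frac: float):
    """(relation, gap) if the pair's geometry admits one, else None."""
    ox = min(fig.x1, cap.x1) - max(fig.x0, cap.x0)
    oy = min(fig.y1, cap.y1) - max(fig.y0, cap.y0)
    if fig.y1 <= cap.y0 and ox >= h_overlap_frac * min(fig.w, cap.w):
        return "caption_below", cap.y0 - fig.y1
    if cap.y1 <= fig.y0 and ox >= h_overlap_frac * min(fig.w, cap.w):
        return "caption_above", fig.y0 - cap.y1
    if oy >= v_overlap_frac * min(fig.h, cap.h) and ox <= 0:
        gap = cap.x0 - fig.x1 if cap.x0 >= fig.x1 else fig.x0 - cap.x1
        return "caption_side", gap
    return None


def associate(
    figures: list[BBox],
    captions: list[CaptionCandidate],
    h_overlap_frac: float = 0.3,
    v_overlap_frac: float = 0.5,
    page: str = "",
) -> tuple[list[FigureCaptionPair], list[CaptionCandidate]]:
    """Greedy minimum-gap assignment, one figure per caption.

    Returns the pairs plus any captions left without an eligible figure.
    """
    edges = []
    for ci, cand in enumerate(captions):
        for fi, fig in enumerate(figures):
            rel = _relation(fig, cand.bbox, h_overlap_frac, v_overlap_frac)
            if rel is not None:
                edges.append((rel[1], ci, fi, rel[0]))
    edges.sort()
    used_c: set[int] = set()
    used_f: set[int] = set()
    pairs: list[FigureCaptionPair] = []
    for gap, ci, fi, rel in edges:
        if ci in used_c or fi in used_f:
            continue
        used_c.add(ci)
        used_f.add(fi)
        fig, cap = figures[fi], captions[ci].bbox
        pairs.append(
            FigureCaptionPair(
                figure=fig,
                caption=cap,
                merged=merge_pair(fig, cap),
                relation=rel,
                caption_text=captions[ci].text,
                page=page,
            )
        )
    unpaired = [c for i, c in enumerate(captions) if i not in used_c]
    pairs.sort(key=lambda p: (p.merged.y0, p.merged.x0))
    return pairs, unpaired


def merge_pair(fig: BBox, cap: BBox) -> BBox:
    """Minimal box containing figure and caption (covers all relations)."""
    return fig.union(cap)


def export_pairs(
    pairs: list[FigureCaptionPair],
    page_image: PageImage,
    out_dir: str | Path,
    page: str = "page",
    extra: dict | None = None,
) -> Path:
    """Write one PNG crop per pair and one JSON record file for the page."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for k, p in enumerate(pairs, start=1):
        crop = page_image.pixels[p.merged.y0 : p.merged.y1, p.merged.x0 : p.merged.x1]
        crop_name = f"{page}_pair{k}.png"
        write_page(out / crop_name, crop)
        records.append(
            {
                "page": page,
                "figure_bbox": p.figure.to_dict(),
                "caption_bbox": p.caption.to_dict(),
                "merged_bbox": p.merged.to_dict(),
                "relation": p.relation,
                "caption_text": p.caption_text,
                "crop": crop_name,
            }
        )
    payload = {"page": page, "pairs": records}
    if extra:
        payload.update(extra)
    path = out / f"{page}_pairs.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path
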