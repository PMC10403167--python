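"""End-to-end page processing: scan in, figure–caption pairs out.

Stage order: grayscale conversion and PSNR-selected enhancement → à-trous
wavelet edge map → connected components / MSER → box expansion, merging and
small-box removal → per-box text/graphic classification with the glyph MLP
→ caption detection and figure association → export.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import Config
from .image import InvalidInputError, PageImage, read_page
from .layout import (
    CaptionCandidate,
    ClassifiedGlyph,
    FigureCaptionPair,
    associate,
    export_pairs,
    find_caption_headers,
    grow_caption,
    group_lines,
    median_line_gap,
)
from .preprocess import select_smoother
from .regions import (
    BBox,
    Region,
    connected_components,
    expand_boxes,
    filter_small,
    merge_overlapping,
    mser_detect,
)
from .textrec import (
    BlockLabel,
    MLPModel,
    classify_block,
    compute_features,
    crop_and_resize,
    text_fraction,
)
from .wavelet import atrous_decompose, edge_map

log = logging.getLogger("figcap")

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class BlockResult:
    bbox: BBox
    label: BlockLabel
    glyphs: list[ClassifiedGlyph] = field(default_factory=list)


@dataclass
class PageResult:
    page: str
    smoother: str
    blocks: list[BlockResult]
    captions: list[CaptionCandidate]
    pairs: list[FigureCaptionPair]
    unpaired_captions: list[CaptionCandidate]

    @property
    def figures(self) -> list[BBox]:
        return [b.bbox for b in self.blocks if b.label.label == "graphic"]

    def to_prediction_dict(self) -> dict:
        return {
            "page": self.page,
            "figures": [b.to_dict() for b in self.figures],
            "captions": [c.bbox.to_dict() for c in self.captions],
            "pairs": [
                {
                    "figure_bbox": p.figure.to_dict(),
                    "caption_bbox": p.caption.to_dict(),
                    "merged_bbox": p.merged.to_dict(),
                    "relation": p.relation,
                    "caption_text": p.caption_text,
                }
                for p in self.pairs
            ],
        }


def _extract_glyphs(
    enhanced: PageImage, box: BBox, model: MLPModel, cfg: Config
) -> tuple[list[ClassifiedGlyph], float]:
    """Character candidates of one block plus the block's text percentage."""
    from skimage.filters import threshold_otsu

    from .textrec import enhance_glyph_mask

    crop = enhanced.pixels[box.y0 : box.y1, box.x0 : box.x1]
    # the dilated+filled mask segments characters (it bridges broken
    # strokes); features are computed from the raw binarized strokes so the
    # classifier sees what it was trained on
    mask = enhance_glyph_mask(crop)
    if not mask.any():
        return [], 0.0
    raw = crop < threshold_otsu(crop)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    objects = ndimage.find_objects(labels)
    size = cfg["textrec.glyph_size"]
    lo, hi = cfg["textrec.glyph_min_px"], cfg["textrec.glyph_max_px"]
    cands: list[tuple[BBox, np.ndarray]] = []
    for i, sl in enumerate(objects, start=1):
        sub = raw[sl] & (labels[sl] == i)
        if not sub.any():
            continue
        ys, xs = np.nonzero(sub)
        h = int(ys.max() - ys.min()) + 1
        w = int(xs.max() - xs.min()) + 1
        if max(h, w) > hi or max(h, w) < lo:
            continue
        glyph = crop_and_resize(sub, size=size)
        gb = BBox(
            y0=box.y0 + sl[0].start + int(ys.min()),
            x0=box.x0 + sl[1].start + int(xs.min()),
            h=h,
            w=w,
        )
        cands.append((gb, compute_features(glyph)))
    if not cands:
        return [], 0.0
    feats = np.stack([f for _, f in cands])
    proba = model.predict_proba(feats)
    best = proba.argmax(axis=1)
    conf = proba[np.arange(len(cands)), best]
    accepted: list[ClassifiedGlyph] = []
    reject_below = cfg["textrec.reject_below"]
    for (gb, _), ci, p in zip(cands, best, conf):
        if p >= reject_below:
            accepted.append(ClassifiedGlyph(bbox=gb, char=model.classes[int(ci)], confidence=float(p)))
    pct = text_fraction(box, [g.bbox for g in accepted])
    return accepted, pct


def detect_blocks(enhanced: PageImage, cfg: Config) -> tuple[list[BBox], list[Region]]:
    """Edge map → regions → expanded, merged, size-filtered candidate boxes."""
    dec = atrous_decompose(enhanced, cfg["wavelet.levels"])
    em = edge_map(dec, cfg["wavelet.scale"], cfg["wavelet.k"])
    if cfg["regions.mode"] == "cc":
        regs = connected_components(em.binary, min_pixels=cfg["regions.min_cc_pixels"])
    elif cfg["regions.mode"] == "mser":
        m = cfg["regions.mser"]
        regs = mser_detect(
            enhanced,
            delta=m["delta"],
            min_area=m["min_area"],
            max_area=m["max_area"],
            max_variation=m["max_variation"],
        )
    else:
        raise InvalidInputError(f"unknown regions.mode {cfg['regions.mode']!r}")
    boxes = expand_boxes(
        [r.bbox for r in regs], cfg["regions.expand_px"], enhanced.height, enhanced.width
    )
    boxes = merge_overlapping(boxes)
    threshold = cfg["regions.min_box_area"]
    if cfg["regions.min_area_mode"] == "box":
        boxes = filter_small(boxes, threshold)
    else:  # pixel-count reading of the area threshold
        kept = []
        for b in boxes:
            npx = sum(
                r.size
                for r in regs
                if b.x0 <= r.bbox.x0 and r.bbox.x1 <= b.x1 and b.y0 <= r.bbox.y0 and r.bbox.y1 <= b.y1
            )
            if npx >= threshold:
                kept.append(b)
        boxes = kept
    return boxes, regs


def run_pipeline(
    image: PageImage | str | Path,
    model: MLPModel,
    config: Config | None = None,
    page: str = "page",
) -> PageResult:
    """Process one page deterministically; see the module docstring."""
    cfg = config or Config()
    img = read_page(image) if not isinstance(image, PageImage) else image
    t0 = time.perf_counter()
    smoother, enhanced = select_smoother(
        img,
        methods=tuple(cfg["smoothing.methods"]),
        mask_size=cfg["smoothing.mask_size"],
        peak=cfg["psnr.peak"],
    )
    log.info("%s: smoother=%s (%.2fs)", page, smoother, time.perf_counter() - t0)

    boxes, _ = detect_blocks(enhanced, cfg)
    log.info("%s: %d candidate boxes", page, len(boxes))

    blocks: list[BlockResult] = []
    for box in boxes:
        glyphs, pct = _extract_glyphs(enhanced, box, model, cfg)
        label = classify_block(box, pct, cfg["textrec.text_threshold_pct"])
        blocks.append(BlockResult(bbox=box, label=label, glyphs=glyphs))

    text_glyphs = [g for b in blocks if b.label.label == "text" for g in b.glyphs]
    lines = group_lines(
        text_glyphs, cfg["layout.word_gap_factor"], cfg["layout.segment_gap_factor"]
    )
    med_gap = median_line_gap(lines)
    captions = [
        grow_caption(c, lines, med_gap, cfg["layout.gap_factor"])
        for c in find_caption_headers(lines)
    ]
    figures = [b.bbox for b in blocks if b.label.label == "graphic"]
    pairs, unpaired = associate(
        figures,
        captions,
        cfg["layout.h_overlap_frac"],
        cfg["layout.v_overlap_frac"],
        page=page,
    )
    log.info(
        "%s: %d figures, %d captions, %d pairs (%.2fs)",
        page,
        len(figures),
        len(captions),
        len(pairs),
        time.perf_counter() - t0,
    )
    return PageResult(
        page=page,
        smoother=smoother,
        blocks=blocks,
        captions=captions,
        pairs=pairs,
        unpaired_captions=unpaired,
    )


def export_result(
    result: PageResult, image: PageImage, out_dir: str | Path, cfg: Config | None = None
) -> Path:
    """Write pair crops plus the page's JSON record (with a config snapshot)."""
    extra = result.to_prediction_dict()
    extra.pop("pairs")  # export_pairs writes the pair records (with crop names)
    extra["smoother"] = result.smoother
    extra["config"] = (cfg or Config()).to_dict()
    return export_pairs(result.pairs, image, out_dir, page=result.page, extra=extra)
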