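import itertools
import json

import numpy as np
import pytest

from figcap.image import PageImage
from figcap.layout import (
    CaptionCandidate,
    ClassifiedGlyph,
    TextLine,
    associate,
    export_pairs,
    find_caption_headers,
    grow_caption,
    group_lines,
    merge_pair,
)
from figcap.regions import BBox


def glyph(x, y, w=10, h=14, char="a"):
    return ClassifiedGlyph(bbox=BBox(y0=y, x0=x, h=h, w=w), char=char, confidence=1.0)


def line_from_text(text, x=0, y=0, w_per_char=12, h=14):
    glyphs = [
        glyph(x + i * w_per_char, y, w=w_per_char - 2, char=c)
        for i, c in enumerate(text)
        if c != " "
    ]
    bbox = BBox(y0=y, x0=x, h=h, w=len(text) * w_per_char)
    return TextLine(bbox=bbox, glyphs=glyphs, text=text)


class TestGroupLines:
    def test_two_baselines_two_lines(self):
        glyphs = [glyph(0, 0), glyph(15, 0), glyph(0, 40), glyph(15, 40)]
        lines = group_lines(glyphs)
        assert len(lines) == 2
        assert lines[0].bbox.y0 == 0 and lines[1].bbox.y0 == 40

    def test_empty(self):
        assert group_lines([]) == []

    def test_rendered_caption_round_trip(self):
        # render "Figure 2." with the package font and feed the true classes
        from figcap import font

        text = "Figure 2."
        glyphs = []
        x = 0
        for c in text:
            if c == " ":
                x += 12
                continue
            bm = font.glyph_bitmap(c, 3)
            ys, xs = np.nonzero(bm)
            glyphs.append(
                ClassifiedGlyph(
                    bbox=BBox(
                        y0=int(ys.min()),
                        x0=x + int(xs.min()),
                        h=int(ys.max() - ys.min() + 1),
                        w=int(xs.max() - xs.min() + 1),
                    ),
                    char=c,
                    confidence=1.0,
                )
            )
            x += 18
        lines = group_lines(glyphs)
        assert len(lines) == 1
        assert lines[0].text.replace(" ", "") == "Figure2."

    def test_wide_gap_splits_segments(self):
        glyphs = [glyph(i * 15, 0) for i in range(5)] + [
            glyph(400 + i * 15, 0) for i in range(5)
        ]
        lines = group_lines(glyphs, segment_gap_factor=2.5)
        assert len(lines) == 2


class TestHeaders:
    @pytest.mark.parametrize(
        "text,header",
        [
            ("Figure 3. Detected boxes", "Figure"),
            ("FIG. 2: results", "FIG"),
            ("FIGURE 12. something", "FIGURE"),
            ("Fig 4 caption", "Fig"),
            ("Figure2.compact", "Figure"),
        ],
    )
    def test_accepted(self, text, header):
        (cand,) = find_caption_headers([line_from_text(text)])
        assert cand.header == header

    @pytest.mark.parametrize(
        "text",
        ["Fight or flight response", "The Figure shows", "figure 2. lowercase", "Figment 9"],
    )
    def test_rejected(self, text):
        assert find_caption_headers([line_from_text(text)]) == []


class TestGrowCaption:
    def make_lines(self, specs):
        # specs: list of (y, text); uniform height 14
        return [line_from_text(t, y=y) for y, t in specs]

    def test_one_line_caption_closes_immediately(self):
        lines = self.make_lines([(0, "Figure 1. A cell."), (100, "body text here")])
        (cand,) = find_caption_headers(lines)
        grown = grow_caption(cand, lines, median_gap=6.0)
        assert grown.closed and len(grown.lines) == 1

    def test_three_tight_lines_attach(self):
        lines = self.make_lines(
            [
                (0, "Figure 2. first line"),
                (20, "middle line of caption"),
                (40, "ends with a period."),
                (140, "far away paragraph"),
            ]
        )
        (cand,) = find_caption_headers(lines)
        grown = grow_caption(cand, lines, median_gap=6.0)
        assert len(grown.lines) == 3
        assert grown.bbox.y1 >= 40

    def test_page_bottom_closes(self):
        lines = self.make_lines([(0, "Figure 3. last thing on page")])
        (cand,) = find_caption_headers(lines)
        grown = grow_caption(cand, lines, median_gap=6.0)
        assert grown.closed and len(grown.lines) == 1


class TestAssociate:
    def test_figure_above_caption(self):
        fig = BBox.from_xywh(10, 10, 200, 150)
        cand = CaptionCandidate(header="Figure", bbox=BBox.from_xywh(10, 190, 200, 30), lines=[])
        (pair,), unpaired = associate([fig], [cand])
        assert pair.relation == "caption_below"
        assert unpaired == []

    def test_caption_above_figure(self):
        fig = BBox.from_xywh(10, 200, 200, 150)
        cand = CaptionCandidate(header="Figure", bbox=BBox.from_xywh(10, 100, 200, 30), lines=[])
        (pair,), _ = associate([fig], [cand])
        assert pair.relation == "caption_above"

    def test_side_caption(self):
        fig = BBox.from_xywh(10, 100, 200, 200)
        cand = CaptionCandidate(header="Figure", bbox=BBox.from_xywh(260, 150, 120, 80), lines=[])
        (pair,), _ = associate([fig], [cand])
        assert pair.relation == "caption_side"

    def test_caption_without_figure_reported(self):
        cand = CaptionCandidate(header="Figure", bbox=BBox.from_xywh(10, 10, 100, 20), lines=[])
        pairs, unpaired = associate([], [cand])
        assert pairs == [] and unpaired == [cand]

    def test_two_stacked_pairs_match_brute_force(self):
        figs = [BBox.from_xywh(10, 0, 200, 100), BBox.from_xywh(10, 300, 200, 100)]
        caps = [
            CaptionCandidate(header="Figure", bbox=BBox.from_xywh(10, 120, 200, 30), lines=[]),
            CaptionCandidate(header="Figure", bbox=BBox.from_xywh(10, 420, 200, 30), lines=[]),
        ]
        pairs, _ = associate(figs, caps)
        got = {(p.figure.y0, p.caption.y0) for p in pairs}
        # brute force: over all one-to-one assignments, minimize total gap
        def total_gap(assign):
            s = 0
            for fi, ci in assign:
                s += abs(caps[ci].bbox.y0 - figs[fi].y1)
            return s

        best = min(
            (list(zip(range(2), perm)) for perm in itertools.permutations(range(2))),
            key=total_gap,
        )
        expected = {(figs[fi].y0, caps[ci].bbox.y0) for fi, ci in best}
        assert got == expected

    def test_pairing_invariant_to_listing_order(self):
        figs = [BBox.from_xywh(10, 0, 200, 100), BBox.from_xywh(10, 300, 200, 100)]
        caps = [
            CaptionCandidate(header="Figure", bbox=BBox.from_xywh(10, 120, 200, 30), lines=[]),
            CaptionCandidate(header="Figure", bbox=BBox.from_xywh(10, 420, 200, 30), lines=[]),
        ]
        a, _ = associate(figs, caps)
        b, _ = associate(figs[::-1], caps[::-1])
        assert {(p.figure, p.caption) for p in a} == {(p.figure, p.caption) for p in b}


class TestMergePair:
    def test_union_arithmetic(self):
        fig = BBox.from_xywh(10, 10, 200, 150)
        cap = BBox.from_xywh(10, 170, 200, 40)
        assert merge_pair(fig, cap) == BBox.from_xywh(10, 10, 200, 200)

    def test_contained_caption(self):
        fig = BBox.from_xywh(0, 0, 100, 100)
        cap = BBox.from_xywh(10, 10, 20, 20)
        assert merge_pair(fig, cap) == fig

    def test_commutative_and_covers_both(self, rng):
        for _ in range(50):
            a = BBox.from_xywh(*(int(v) for v in rng.integers(0, 50, 2)), *(int(v) for v in rng.integers(1, 40, 2)))
            b = BBox.from_xywh(*(int(v) for v in rng.integers(0, 50, 2)), *(int(v) for v in rng.integers(1, 40, 2)))
            m = merge_pair(a, b)
            assert m == merge_pair(b, a)
            assert m.area >= max(a.area, b.area)
            assert m.x0 <= min(a.x0, b.x0) and m.y1 >= max(a.y1, b.y1)


class TestExport:
    def _pair(self):
        from figcap.layout import FigureCaptionPair

        fig = BBox.from_xywh(5, 5, 40, 30)
        cap = BBox.from_xywh(5, 40, 40, 10)
        return FigureCaptionPair(
            figure=fig, caption=cap, merged=merge_pair(fig, cap), relation="caption_below"
        )

    def test_single_pair_outputs(self, tmp_path):
        img = PageImage(np.full((80, 80), 200.0))
        path = export_pairs([self._pair()], img, tmp_path, page="p1")
        d = json.loads(path.read_text())
        assert len(d["pairs"]) == 1
        assert (tmp_path / "p1_pair1.png").exists()

    def test_no_pairs(self, tmp_path):
        img = PageImage(np.full((40, 40), 200.0))
        path = export_pairs([], img, tmp_path, page="p2")
        d = json.loads(path.read_text())
        assert d["pairs"] == []
        assert list(tmp_path.glob("*.png")) == []

    def test_crop_dimensions(self, tmp_path):
        import imageio.v3 as iio

        img = PageImage(np.full((80, 80), 200.0))
        pair = self._pair()
        export_pairs([pair], img, tmp_path, page="p3")
        crop = iio.imread(tmp_path / "p3_pair1.png")
        assert crop.shape == (pair.merged.h, pair.merged.w)
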