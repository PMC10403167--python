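import numpy as np
import pytest
from scipy import ndimage

from figcap import font
from figcap.image import InvalidInputError
from figcap.regions import BBox
from figcap.textrec import (
    EmptyGlyphError,
    MLPModel,
    classify_block,
    classify_glyph,
    compute_features,
    crop_and_resize,
    enhance_glyph_mask,
    text_fraction,
    train_mlp,
)


class TestGlyphMask:
    def test_blank_crop_gives_empty_mask(self):
        assert not enhance_glyph_mask(np.full((10, 10), 200.0)).any()

    def test_ring_is_filled(self):
        arr = np.full((20, 20), 255.0)
        arr[5:15, 5:15] = 0.0
        arr[8:12, 8:12] = 255.0  # hole of an 'O'
        mask = enhance_glyph_mask(arr)
        assert mask[10, 10]  # hole filled

    def test_thin_stroke_dilates(self):
        arr = np.full((15, 15), 255.0)
        arr[3:12, 7] = 0.0  # 1-px stroke
        mask = enhance_glyph_mask(arr)
        # brute-force 3x3 dilation oracle on the binarized stroke
        expected = ndimage.binary_dilation(arr < 128, np.ones((3, 3), bool))
        assert mask[3:12, 6:9].all()
        assert (mask & ~expected).sum() == 0


class TestCropAndResize:
    def test_tight_square_identity(self):
        grid = np.ones((32, 32), dtype=bool)
        assert np.array_equal(crop_and_resize(grid, 32).grid, grid)

    def test_margins_removed_matches_tight_bbox_oracle(self):
        bm = font.glyph_bitmap("P", 4)
        padded = np.pad(bm, 2)
        ys, xs = np.nonzero(padded)
        tight = padded[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
        a = crop_and_resize(padded, 32).grid
        b = crop_and_resize(tight, 32).grid
        assert np.array_equal(a, b)

    def test_single_pixel_upscales_to_full(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        assert crop_and_resize(grid, 16).grid.all()

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyGlyphError):
            crop_and_resize(np.zeros((4, 4), dtype=bool))


class TestFeatures:
    def test_solid_square_symmetry(self):
        f = compute_features(np.ones((32, 32), dtype=bool))
        # full symmetry about the box centre kills the odd moments
        assert np.allclose(f[[5, 6, 9, 10, 11]], 0.0, atol=1e-12)
        assert f[12] == 1.0  # one run per row

    def test_solid_square_hand_values(self):
        f = compute_features(np.ones((32, 32), dtype=bool))
        # hand-computed: W=H=32, count=1024, var of 0..31 is 85.25
        assert f[2] == 32 and f[3] == 32 and f[4] == 1024
        assert np.isclose(f[7], 85.25 / 32**2)
        assert np.isclose(f[8], 85.25 / 32**2)
        assert f[13] == sum(range(32))  # one run start per row
        assert f[14] == 1.0
        assert f[15] == sum(range(32))

    def test_two_bars_have_two_row_transitions(self):
        grid = np.zeros((16, 16), dtype=bool)
        grid[:, 4:6] = True
        grid[:, 10:12] = True
        f = compute_features(grid)
        assert f[12] == 2.0

    def test_left_heavy_f_is_negative_f6(self):
        f = compute_features(crop_and_resize(font.glyph_bitmap("F", 3)).grid)
        assert f[5] < 0

    def test_wide_spread_m_beats_i_on_f8(self):
        f_m = compute_features(crop_and_resize(font.glyph_bitmap("M", 3)).grid)
        f_i = compute_features(crop_and_resize(font.glyph_bitmap("I", 3)).grid)
        assert f_m[7] > f_i[7]

    def test_invariant_to_blank_border_before_crop(self):
        bm = font.glyph_bitmap("R", 3)
        a = compute_features(crop_and_resize(bm))
        b = compute_features(crop_and_resize(np.pad(bm, 5)))
        assert np.allclose(a, b)

    def test_empty_glyph_raises(self):
        with pytest.raises(EmptyGlyphError):
            compute_features(np.zeros((8, 8), dtype=bool))


def _blob_dataset(seed=0, n=40):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.3, (n, 16)) + np.r_[np.ones(8), np.zeros(8)]
    b = rng.normal(0, 0.3, (n, 16)) + np.r_[np.zeros(8), np.ones(8)]
    return [(x, "a") for x in a] + [(x, "b") for x in b]


class TestMLP:
    def test_separable_blobs_reach_full_accuracy(self):
        data = _blob_dataset()
        # brute-force check that a single linear scan separates the classes
        score = np.array([x[:8].sum() - x[8:].sum() for x, _ in data])
        labels = np.array([c for _, c in data])
        assert (score[labels == "a"] > 0).all() and (score[labels == "b"] < 0).all()
        model = train_mlp(data, hidden=8, epochs=200, seed=0)
        X = np.stack([x for x, _ in data])
        pred = model.predict_proba(X).argmax(1)
        assert all(model.classes[p] == c for p, c in zip(pred, labels))

    def test_retraining_is_bit_identical(self):
        data = _blob_dataset(seed=3)
        m1 = train_mlp(data, hidden=8, epochs=50, seed=7)
        m2 = train_mlp(data, hidden=8, epochs=50, seed=7)
        for a, b in zip(m1.coefs, m2.coefs):
            assert np.array_equal(a, b)
        for a, b in zip(m1.intercepts, m2.intercepts):
            assert np.array_equal(a, b)

    def test_xor_is_learnable(self):
        pts = [([0.0, 0.0], "n"), ([1.0, 1.0], "n"), ([0.0, 1.0], "y"), ([1.0, 0.0], "y")]
        rng = np.random.default_rng(0)
        data = []
        for _ in range(40):
            for x, c in pts:
                data.append((np.array(x) + rng.normal(0, 0.02, 2), c))
        model = train_mlp(data, hidden=8, epochs=2000, lr=0.1, seed=1)
        X = np.stack([x for x, _ in data])
        pred = model.predict_proba(X).argmax(1)
        assert all(model.classes[p] == c for p, (_, c) in zip(pred, data))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            train_mlp([(np.zeros(16), "a")] * 4)

    def test_json_roundtrip(self):
        model = train_mlp(_blob_dataset(), hidden=4, epochs=20, seed=0)
        clone = MLPModel.from_json(model.to_json())
        X = np.stack([x for x, _ in _blob_dataset(seed=9, n=5)])
        assert np.allclose(model.predict_proba(X), clone.predict_proba(X))


class TestClassifyGlyph:
    def test_confident_class_accepted(self):
        model = train_mlp(_blob_dataset(), hidden=8, epochs=200, seed=0)
        x = np.r_[np.ones(8), np.zeros(8)]
        cls, p = classify_glyph(model, x, reject_below=0.5)
        assert cls == "a" and p >= 0.5

    def test_low_confidence_rejected(self):
        model = train_mlp(_blob_dataset(), hidden=8, epochs=200, seed=0)
        cls, p = classify_glyph(model, np.full(16, 0.5), reject_below=0.999)
        assert cls is None

    def test_wrong_feature_length_raises(self):
        model = train_mlp(_blob_dataset(), hidden=4, epochs=20, seed=0)
        with pytest.raises(InvalidInputError):
            classify_glyph(model, np.zeros(5))

    def test_rendered_glyph_self_consistency(self, glyph_model_full):
        # noiseless renderings of the header-critical characters must read
        # back as themselves (case pairs such as u/U are a known confusion
        # of the size-normalized descriptor and are not required here)
        from figcap.textrec import compute_features as cf

        for char in "AFig2":
            feats = cf(crop_and_resize(font.glyph_bitmap(char, 3)))
            cls, _ = classify_glyph(glyph_model_full, feats)
            assert cls == char, f"{char!r} read as {cls!r}"


class TestBlockClassification:
    def test_no_glyphs_zero_percent(self):
        assert text_fraction(BBox.from_xywh(0, 0, 100, 100), []) == 0.0

    def test_half_coverage(self):
        box = BBox.from_xywh(0, 0, 100, 100)
        glyphs = [BBox.from_xywh(0, 0, 100, 50)]
        assert text_fraction(box, glyphs) == 50.0

    def test_arithmetic_example(self):
        box = BBox.from_xywh(0, 0, 100, 200)
        glyphs = [BBox.from_xywh(0, 0, 60, 50)]  # 3000 px²
        assert text_fraction(box, glyphs) == 15.0

    @pytest.mark.parametrize(
        "pct,expected",
        [(15.0, "graphic"), (25.0, "text"), (20.0, "text")],  # strict less-than
    )
    def test_threshold_rule(self, pct, expected):
        assert classify_block(BBox.from_xywh(0, 0, 10, 10), pct, 20.0).label == expected
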