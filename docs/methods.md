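# Methods

This note documents the models, parameters, and design choices behind
`figcap`, and what the synthetic benchmark does and does not demonstrate.

## Pre-processing

Grayscale conversion uses the weights (0.2989, 0.5878, 0.1140). They sum
to 1.0007, so a pure-white pixel maps to 255.18 before clipping; the
implementation applies the weights as given and clips to [0, 255] rather
than renormalising, and the tests pin this behaviour.

Three smoothers share a square mask (`smoothing.mask_size`, default 7):

* **wiener** — local adaptive minimum-MSE (Lee) filter: output is the local
  mean plus the residual scaled by `max(σ²−ν, 0)/max(σ², ν)`, where σ² is
  the local variance and ν the page-wide mean local variance. It is written
  on top of `uniform_filter` rather than `scipy.signal.wiener` because the
  latter zero-pads borders; all window filters here use mirror reflection
  so page margins do not acquire dark halos that later become spurious
  edge components.
* **median**, **lowpass** — windowed median and mean.

The smoother is selected per page by the PSNR of (smooth → unsharp) output
against the grayscale input, `PSNR = 10·log₁₀(G²/MSE)` with peak G = 255
(`psnr.peak`; the "overall gray level" is read as the peak representable
value). Identical images report an infinite-PSNR sentinel that compares
greater than any finite value; ties resolve wiener > median > lowpass. On
Gaussian-noise pages the adaptive Wiener filter wins consistently, matching
its role as the default. PSNR is measured against the *sharpened* image;
measuring against the smoothed image instead is a one-line change in
`select_smoother`.

The unsharp mask is the Laplacian-subtraction kernel
`[[0,−1,0],[−1,5,−1],[0,−1,0]]` (unit DC gain, configurable via
`unsharp.kernel`); the original operator's exact coefficients are not
documented, and any unit-gain sharpening kernel serves the stated purpose
of boosting edge information.

## À-trous wavelet edges

Level j smooths with the B3 cubic-spline kernel — the outer product of
(1,4,6,4,1)/16 — dilated by inserting 2^(j−1)−1 zeros between taps;
convolution is separable, mirror-padded, never subsampled. Detail planes
are `D_j = A_{j−1} − A_j`, so reconstruction `A_N + Σ D_j` telescopes and
is exact to floating-point rounding (asserted at ≤ 1e−9). Away from
borders the transform commutes with translations.

Edge maps threshold `|D_scale|` at `k · median(|D|)/0.6745`, a MAD-style
robust estimate of k standard deviations of the detail noise (`wavelet.k`,
default 3; `wavelet.scale`, default 2; `wavelet.levels`, default 3). The
binarisation rule and the working scale are this package's choices: scale 1
is dominated by pixel noise, scale 2 keeps glyph-level strokes while
suppressing it. A featureless plane yields an empty map, not an all-true
one.

## Regions

Default region source is 8-connected components of the binary edge map.
Components smaller than `regions.min_cc_pixels` (25) are dropped first:
supra-threshold noise pixels are isolated singletons, but once each is
expanded by 5 px their boxes chain-merge across the page (11×11 boxes at
~0.3% density percolate), so a small pre-filter is required for the
expand–merge–filter chain to behave. Real strokes and figure outlines are
far above 25 edge pixels at the working resolutions.

Boxes are then expanded by `regions.expand_px` (5), merged to a fixpoint
(connected components of the box-overlap graph, iterated because unions
can create new overlaps; shared edges count as overlap), and filtered at
`regions.min_box_area` (7,000 px², the operating point for page images
around 850×1100 and up). The threshold is applied to merged-box area;
`regions.min_area_mode = "pixels"` switches it to the summed pixel count
of the regions inside each box, for the reading under which the area of
the *regions* is thresholded.

An MSER detector (`regions.mode = "mser"`) is available for graded inputs.
It sweeps intensity levels with union-find, identifying each component-tree
branch by its seed (the lexicographically smallest (intensity, y, x)
pixel), and records component sizes at end-of-level snapshots. Stability at
level t is `(A(t+Δ) − A(t−Δ))/A(t)` along the branch, with A := 0 before
the branch is born; regions are local minima of this score with value
≤ `max_variation` and area within `[min_area, max_area]`
(defaults Δ = 5, 30 px, 0.9 × page, 0.5). Both polarities are detected by
inverting the image; the full-image component has no outer boundary and is
never extremal. On binary edge maps MSER degenerates (two levels), which is
why plain connected components are the pipeline default. The test suite
holds the detector equal to an independently coded oracle that thresholds
at all 256 levels.

Coordinates everywhere are 0-based, half-open boxes, x rightward, y
downward.

## Glyph recognition

Inside each candidate box the crop is binarized (Otsu), dilated 3×3, and
hole-filled. This *segmentation* mask bridges broken strokes and detached
dots so each character is one component; features are computed from the raw
binarized strokes inside each component, because hole-filling would turn
every loop letter into a solid blob and erase its identity. Components
whose stroke extent is outside [`glyph_min_px`, `glyph_max_px`] (3, 80) are
not characters (noise specks, figure fragments) and are discarded.

Each glyph is cropped tight and resized (nearest neighbour) to 32×32
(`textrec.glyph_size`). The 16-feature descriptor comprises box
position/size (constant on the normalized grid, kept for fidelity to the
classic letter-recognition descriptor), on-pixel count, first- to
third-order moments of on-pixels about the *box centre* scaled by box
width/height (the mass-centroid reading would make the first moments
identically zero; the box-centre reading gives the documented behaviour,
e.g. a negative horizontal moment for the left-heavy 'F'), and row/column
stroke-edge scan statistics with y measured upward from the box bottom.

The classifier is an MLP (16 → 64 logistic units → softmax over classes)
trained by seeded mini-batch SGD (lr 0.05, momentum 0.9, batch 64,
400 epochs) on z-scored features, via scikit-learn; the forward pass used
at classification time is re-implemented in numpy so models serialize to
versioned JSON (weights, class alphabet, feature standardization) with no
trainer dependency. Training is bit-reproducible for a fixed seed. The
width and epoch count were fixed by validation on the font dataset, where
accuracy plateaus near 92%; the residual errors are case pairs (u/U, o/O,
x/X) that size normalization makes genuinely ambiguous. Glyphs below
probability `textrec.reject_below` (0.5) are rejected as non-text.

A box is **graphic** when accepted-glyph tight-box area covers less than
`textrec.text_threshold_pct` (20%) of it, **text** otherwise (a ratio the
other way around would exceed 1 and contradict the "less than threshold"
rule, so text-area/box-area is the only consistent reading; exactly 20% is
text, the rule being a strict less-than).

## Layout

Glyphs of text boxes are grouped into lines by ≥ 50% vertical overlap of
the smaller box; horizontal gaps beyond 1.5× the median glyph width become
spaces, and gaps beyond `layout.segment_gap_factor` × median width (2.5,
roughly a column gutter) split the row — without the split, captions of
adjacent columns that share a baseline would fuse into one pseudo-line and
both be lost.

A caption opens at a line matching `^(Figure|FIGURE|Fig|FIG)[.:]?` followed
by a digit within the next few characters (the digit requirement rejects
prose like "Fight or flight"). It grows with the next horizontally
overlapping line while the vertical gap stays within `layout.gap_factor`
(1.5) × the page's median line gap, and closes at a paragraph-scale gap or
page end; the terminal-period rule is kept but in practice the gap
criterion closes blocks, since a period misread does not then orphan the
caption.

Figure association scores all (caption, figure) combinations admitting one
of three relations — caption below the figure, above it (each requiring
≥ 30% horizontal overlap of the narrower box), or at its side (≥ 50%
vertical overlap of the shorter box, no horizontal overlap) — and resolves
conflicts greedily by ascending gap, one caption per figure. A pair is
exported as the minimal box containing both, which covers all three
relations by a single rule. Unpaired captions are reported but not
cropped.

## Synthetic benchmark

The generator emulates book pages: 850×1100 px (the small end of realistic
scan sizes, chosen so the 50-page end-to-end check runs in about a
minute), 60 px margins, body text from the built-in 5×7 bitmap font scaled
×3 (glyphs 15×21 px, 6 px line gap, 34 px element separation, 44 px column
gutter), figures of 200–330 px height filled with smoothed noise, outlined
shape panels, or a framed gradient, one caption per figure ("Figure N."
plus random words, ending with a period, below/above the figure), and
additive Gaussian noise of σ = 5 applied last. Presets: `simple` (one
pair, single column), `multi_panel` (1–2 figures, captions below or
above), `two_column` (pairs confined to columns), and `mixed` cycling all
three. Ground truth is exact by construction.

The font is part of the package so glyph ground truth needs no font files.
Every glyph is a single 8-connected component, and case pairs that differ
only by size in ordinary typefaces are drawn with distinct shapes, because
the recognizer normalizes size away. The dash is excluded from the
recognizer alphabet ('.' and '-' both normalize to a solid block); the
pipeline alphabet extends the 62 letters and digits with `. , ( )` so the
caption-terminating period is observable. Glyph training data jitters each
bitmap by ±2 px shift, ±15% scale, and 2% salt-pixel flips.

What the generator does **not** model: real typefaces and anti-aliased
rasterization, skew and curvature, bleed-through, JPEG artifacts, tables,
display equations, compound-figure panel splitting, and captions sharing a
block with body text. Passing the synthetic benchmark therefore shows the
stages compose correctly and the geometry/recognition logic is sound at
realistic noise levels — not that the tuned thresholds transfer unchanged
to arbitrary scanned books.

## Numerical and degenerate-input conventions

Infinite PSNR is an explicit sentinel; undefined precision/recall (zero
denominators) are reported as `None`, never silent zeros. Constant images
produce empty edge maps, no MSERs, and empty glyph masks without error.
Blank pages exit cleanly with zero pairs. All randomness (generator,
training, jitter) flows from explicit seeds; reruns are bit-identical.

## Known limitations

* OCR is intentionally minimal: 16 coarse features per glyph, one built-in
  font. Case confusions (u/U, o/O) and period-as-letter misreads occur and
  caption *text* is therefore approximate; box-level extraction is what is
  scored.
* The caption grammar covers `Fig…/Figure…` headers with Arabic numerals
  only; multi-page captions and table captions are out of scope.
* MSER on full-resolution pages is a pure-Python sweep and is noticeably
  slower than the default connected-component path.
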