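"""Glyph normalization, the 16-feature character descriptor, and the MLP.

Each candidate layout block is probed for text: the block crop is
binarized and morphologically cleaned, its connected components are treated
as character candidates, each is cropped tight and resized to a fixed S×S
grid, and a 16-element descriptor of the classic letter-recognition kind
(pixel moments about the box centre plus stroke-edge scan statistics) is
fed to a small multi-layer perceptron.  The fraction of the block covered
by accepted character boxes then decides text vs graphic: blocks whose text
coverage falls below a threshold (20% by default) are graphic elements.

Feature conventions: x runs rightward, y upward from the box bottom, and
moment features are measured from the centre of the tight box and
normalized by the box width/height.  On the normalized grid the box
position/size features f1-f4 are constants; they are kept so the
descriptor stays the full 16-vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .image import InvalidInputError, InvalidParameterError, PageImage
from .regions import BBox

DEFAULT_GLYPH_SIZE = 32


class EmptyGlyphError(InvalidInputError):
    pass


@dataclass
class Glyph:
    """A normalized character bitmap with its tight box in page coordinates."""

    grid: np.ndarray  # (S, S) bool
    bbox: BBox | None = None


def enhance_glyph_mask(crop: PageImage | np.ndarray) -> np.ndarray:
    """Binarize a block crop (dark ink on light paper), dilate, fill holes."""
    arr = crop.pixels if isinstance(crop, PageImage) else np.asarray(crop, dtype=np.float64)
    if arr.max() == arr.min():
        return np.zeros(arr.shape, dtype=bool)
    t = threshold_otsu(arr)
    mask = arr < t
    mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))
    return ndimage.binary_fill_holes(mask)


def crop_and_resize(mask: np.ndarray, size: int = DEFAULT_GLYPH_SIZE) -> Glyph:
    """Crop to the tight box of the on-pixels and nearest-neighbor resize."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyGlyphError("cannot normalize an empty glyph mask")
    ys, xs = np.nonzero(mask)
    tight = mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    h, w = tight.shape
    ri = np.minimum((np.arange(size) + 0.5) * h / size, h - 1).astype(int)
    ci = np.minimum((np.arange(size) + 0.5) * w / size, w - 1).astype(int)
    grid = tight[np.ix_(ri, ci)]
    return Glyph(grid=grid)


def compute_features(glyph: Glyph | np.ndarray) -> np.ndarray:
    """The 16-element descriptor of a normalized glyph.

    f1/f2  box-centre position (from left / from bottom)
    f3/f4  box width / height
    f5     on-pixel count
    f6/f7  mean x / y offset from the box centre, scaled by W / H
    f8/f9  mean squared offsets
    f10    mean xy offset product (sign separates the two diagonals)
    f11/f12 third-order cross moments (variance vs. position correlations)
    f13/f14 mean off→on transitions per row scan; sum of their heights
    f15/f16 mean off→on transitions per column scan (bottom-up); sum of
            their horizontal positions
    """
    grid = glyph.grid if isinstance(glyph, Glyph) else np.asarray(glyph, dtype=bool)
    if not grid.any():
        raise EmptyGlyphError("empty glyph has no features")
    h, w = grid.shape
    rows, cols = np.nonzero(grid)
    x = cols.astype(np.float64)
    y = (h - 1 - rows).astype(np.float64)  # upward from the bottom
    cx = (w - 1) / 2.0
    cy = (h - 1) / 2.0
    dx = (x - cx) / w
    dy = (y - cy) / h

    # row scans, left to right: on-pixel whose left neighbour is off/boundary
    left_off = np.zeros_like(grid)
    left_off[:, 0] = grid[:, 0]
    left_off[:, 1:] = grid[:, 1:] & ~grid[:, :-1]
    e_rows = np.nonzero(left_off)[0]
    # column scans, bottom to top: on-pixel whose lower neighbour is off/boundary
    below_off = np.zeros_like(grid)
    below_off[-1, :] = grid[-1, :]
    below_off[:-1, :] = grid[:-1, :] & ~grid[1:, :]
    v_rows, v_cols = np.nonzero(below_off)

    return np.array(
        [
            cx,
            cy,
            float(w),
            float(h),
            float(len(x)),
            dx.mean(),
            dy.mean(),
            (dx**2).mean(),
            (dy**2).mean(),
            (dx * dy).mean(),
            (dx**2 * dy).mean(),
            (dy**2 * dx).mean(),
            len(e_rows) / h,
            float((h - 1 - e_rows).sum()),
            len(v_rows) / w,
            float(v_cols.sum()),
        ]
    )


@dataclass
class MLPModel:
    """A trained glyph classifier serializable to plain JSON.

    Weights come from a logistic-hidden / softmax-output network; the
    forward pass used at classification time is implemented here so a saved
    model is independent of the trainer.
    """

    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    classes: list[str]
    feat_mean: np.ndarray
    feat_std: np.ndarray
    seed: int = 0
    version: int = 1

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if f.shape[1] != len(self.feat_mean):
            raise InvalidInputError(
                f"expected {len(self.feat_mean)} features, got {f.shape[1]}"
            )
        a = (f - self.feat_mean) / self.feat_std
        for w, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            a = 1.0 / (1.0 + np.exp(-(a @ w + b)))
        z = a @ self.coefs[-1] + self.intercepts[-1]
        if z.shape[1] == 1:  # binary nets have a single logistic output
            p = 1.0 / (1.0 + np.exp(-z[:, 0]))
            return np.column_stack([1.0 - p, p])
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "classes": self.classes,
                "feat_mean": self.feat_mean.tolist(),
                "feat_std": self.feat_std.tolist(),
                "coefs": [c.tolist() for c in self.coefs],
                "intercepts": [b.tolist() for b in self.intercepts],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            coefs=[np.array(c) for c in d["coefs"]],
            intercepts=[np.array(b) for b in d["intercepts"]],
            classes=list(d["classes"]),
            feat_mean=np.array(d["feat_mean"]),
            feat_std=np.array(d["feat_std"]),
            seed=int(d.get("seed", 0)),
            version=int(d.get("version", 1)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train_mlp(
    dataset: list[tuple[np.ndarray, str]],
    hidden: int = 64,
    epochs: int = 400,
    lr: float = 0.05,
    seed: int = 0,
) -> MLPModel:
    """Train the glyph MLP by seeded mini-batch SGD on cross-entropy.

    Features are z-scored with statistics stored in the model; training is
    deterministic for a fixed seed and data order.
    """
    if len(dataset) == 0:
        raise InvalidInputError("empty training set")
    X = np.array([f for f, _ in dataset], dtype=np.float64)
    y = np.array([c for _, c in dataset])
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise InvalidInputError("training set must contain at least two classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    net = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="sgd",
        learning_rate_init=lr,
        batch_size=min(64, len(dataset)),
        max_iter=epochs,
        momentum=0.9,
        nesterovs_momentum=True,
        shuffle=True,
        random_state=seed,
        tol=0.0,
        n_iter_no_change=epochs,
        alpha=1e-4,
    )
    with warnings.catch_warnings():
        # a fixed epoch budget is intentional, not a convergence failure
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit((X - mean) / std, y)
    return MLPModel(
        coefs=[np.array(c) for c in net.coefs_],
        intercepts=[np.array(b) for b in net.intercepts_],
        classes=[str(c) for c in net.classes_],
        feat_mean=mean,
        feat_std=std,
        seed=seed,
    )


def classify_glyph(
    model: MLPModel, features: np.ndarray, reject_below: float = 0.5
) -> tuple[str | None, float]:
    """Best class and its probability; None when below the reject threshold."""
    proba = model.predict_proba(features)[0]
    best = int(np.argmax(proba))
    p = float(proba[best])
    if p < reject_below:
        return None, p
    return model.classes[best], p


def text_fraction(box: BBox, glyph_boxes: list[BBox]) -> float:
    """Percentage of the block box covered by accepted glyph tight boxes."""
    if box.area <= 0:
        raise InvalidInputError("block box must have positive area")
    total = sum(g.area for g in glyph_boxes)
    return min(100.0, 100.0 * total / box.area)


@dataclass(frozen=True)
class BlockLabel:
    label: str  # "text" or "graphic"
    text_fraction: float


def classify_block(box: BBox, pct: float, threshold: float = 20.0) -> BlockLabel:
    """Graphic iff the text percentage is strictly below the threshold."""
    if not (0.0 <= pct <= 100.0):
        raise InvalidParameterError("text percentage must be in [0, 100]")
    return BlockLabel(label="graphic" if pct < threshold else "text", text_fraction=pct)
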