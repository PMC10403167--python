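import numpy as np
import pytest

from figcap import font
from figcap.synthetic import render_glyph_dataset
from figcap.textrec import compute_features, crop_and_resize, train_mlp


def featurize(dataset):
    return [(compute_features(crop_and_resize(bm)), c) for bm, c in dataset]


@pytest.fixture(scope="session")
def glyph_model_full():
    """Pipeline recognizer over the full alphabet (letters, digits, punctuation)."""
    data = render_glyph_dataset(font.ALPHABET_FULL, samples_per_class=120, seed=0)
    return train_mlp(featurize(data), seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
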