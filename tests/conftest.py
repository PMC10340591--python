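import numpy as np
import pytest

from berryprint import FruitFeatureExtractor, LabeledDataset
from berryprint.synthetic import generate_dataset, identical_recipes


def make_ellipse_image(size=64, a=22.0, b=14.0, value=200.0, gradient=True):
    """Gray ellipse on a zero canvas; a mild intensity gradient breaks the
    symmetry so odd-order moments are nonzero."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    mask = ((xx - c) ** 2 / a**2 + (yy - c) ** 2 / b**2) <= 1.0
    img = np.zeros((size, size))
    img[mask] = value
    if gradient:
        img[mask] += 0.4 * (xx + 2 * yy)[mask]
    return img


@pytest.fixture(scope="session")
def ellipse_image():
    return make_ellipse_image()


def features_for(dataset):
    X = FruitFeatureExtractor().fit().transform(dataset.images)
    return LabeledDataset(X, np.array(dataset.labels), np.array(dataset.ids))


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 4-class × 90-image synthetic study set."""
    return generate_dataset(per_class=90, seed=1)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    return features_for(default_dataset)


@pytest.fixture(scope="session")
def degenerate_features():
    """Four identically-parameterized classes: unlearnable by construction."""
    return features_for(generate_dataset(identical_recipes(), per_class=90, seed=2))


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap 4×6 image set for pipeline-level tests."""
    return generate_dataset(per_class=6, seed=3)
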