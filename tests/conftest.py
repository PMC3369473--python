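import numpy as np
import pytest

from tonguelab.classify import LabeledSample
from tonguelab.region import TongueImage
from tonguelab.simulate import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_pixels(rng):
    """10,000 random 8-bit RGB triples."""
    return rng.integers(0, 256, size=(10_000, 3))


@pytest.fixture
def uniform_image():
    """A 20x20 image of one constant color with a full mask."""
    pixels = np.full((20, 20, 3), (180, 90, 60), dtype=np.uint8)
    return TongueImage(pixels=pixels, mask=np.ones((20, 20), bool), id="u")


@pytest.fixture
def blobs_2d(rng):
    """Linearly separable 2-D blobs, labels +1/-1."""
    n = 40
    xa = rng.normal((2.0, 2.0), 0.5, size=(n, 2))
    xb = rng.normal((-2.0, -2.0), 0.5, size=(n, 2))
    X = np.vstack([xa, xb])
    y = np.array([1] * n + [-1] * n)
    return X, y


@pytest.fixture(scope="session")
def small_cohort():
    """A small separable synthetic cohort (session-scoped for speed)."""
    config = CohortConfig(
        n_per_class={1: 18, -1: 12}, image_size=(48, 48), seed=7)
    return generate_cohort(config)


def make_samples(X, y, scheme="test"):
    return [LabeledSample(x=x, y=int(lab), scheme=scheme)
            for x, lab in zip(X, y)]
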