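import numpy as np
import pytest

from mcadenoise import GrayImage, McaConfig, PhantomSpec, make_phantom, mca_decompose


@pytest.fixture(scope="session")
def default_phantom():
    """The default 256x256 phantom with its ground-truth layers."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_phantom_decomposition(default_phantom):
    """Decomposition of the default clean phantom under default solver settings."""
    clean, _, _ = default_phantom
    return mca_decompose(clean)


@pytest.fixture(scope="session")
def small_phantom():
    """A 64x64 phantom for fast tests."""
    return make_phantom(PhantomSpec(size=64, texture_frequency=16.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_unit_image(rng):
    return GrayImage(rng.random((64, 64)), "unit")


def capture_fraction(part: np.ndarray, layer: np.ndarray) -> float:
    """Fraction of a ground-truth layer's energy present in a decomposition part.

    The layer's energy captured by ``part`` is the squared norm of the
    projection of ``part`` onto the layer direction, relative to the layer's
    own energy: (<part, layer> / <layer, layer>)^2.
    """
    denom = float(np.sum(layer * layer))
    return (float(np.sum(part * layer)) / denom) ** 2
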