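import numpy as np
import pytest

from canopyseg.dataset import PixelDataset, assemble
from canopyseg.synthgen import GLASSHOUSE, generate_patchset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_rgb(rng, h=8, w=8):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


def random_mask(rng, h, w):
    return (rng.integers(0, 2, size=(h, w)) * 255).astype(np.uint8)


@pytest.fixture(scope="session")
def glasshouse_pixels():
    """Small assembled pixel dataset from synthetic glasshouse patches."""
    patches = generate_patchset(GLASSHOUSE, 30, 30, seed=7)
    return assemble(patches)


@pytest.fixture(scope="session")
def separable_pixels():
    """Two disjoint color clusters in 2 feature channels; linearly separable."""
    rng = np.random.default_rng(0)
    n = 600
    fg = np.clip(rng.normal([0.75, 0.25], 0.03, size=(n, 2)), 0, 1)
    bg = np.clip(rng.normal([0.25, 0.75], 0.03, size=(n, 2)), 0, 1)
    X = np.vstack([fg, bg])
    y = np.r_[np.ones(n, dtype=np.uint8), np.zeros(n, dtype=np.uint8)]
    return PixelDataset(X, y, ("rgb.G", "rgb.R"))
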