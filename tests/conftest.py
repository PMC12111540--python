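import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def random_histograms(rng):
    """Sparse-ish random 256-bin count vectors with at least two nonzero bins."""
    hists = []
    for _ in range(50):
        h = np.zeros(256, dtype=np.int64)
        n_bins = int(rng.integers(2, 40))
        bins = rng.choice(256, size=n_bins, replace=False)
        h[bins] = rng.integers(1, 500, size=n_bins)
        hists.append(h)
    return hists


@pytest.fixture
def random_small_images(rng):
    """Small random gray images with a handful of distinct levels."""
    images = []
    for _ in range(10):
        shape = (int(rng.integers(8, 17)), int(rng.integers(8, 17)))
        levels = rng.choice(256, size=int(rng.integers(2, 6)), replace=False)
        images.append(rng.choice(levels, size=shape).astype(np.int64))
    return images
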