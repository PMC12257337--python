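import numpy as np
import pytest

import acrlcod as al
from acrlcod.segmentation import normalize_slice, segment_inner_disk


@pytest.fixture(scope="session")
def layout():
    return al.PhantomLayout.default()


@pytest.fixture(scope="session")
def clean_slice11():
    """High-SNR LCOD slice (5.1% contrast) with ground truth."""
    cfg = al.SimulationConfig(seed=5, snr=400)
    return al.simulate_slice(cfg, 11)


@pytest.fixture(scope="session")
def noisefree_slice11():
    cfg = al.SimulationConfig(seed=0, snr=None)
    return al.simulate_slice(cfg, 11)


@pytest.fixture(scope="session")
def segmented11(clean_slice11):
    slc, truth = clean_slice11
    norm = normalize_slice(slc)
    mask = segment_inner_disk(norm)
    return norm, mask, truth


@pytest.fixture(scope="session")
def noisy_volume():
    """A realistic noisy volume (nominal contrasts, SNR 300)."""
    cfg = al.SimulationConfig(seed=9, snr=300)
    vol, truth = al.simulate_volume(cfg)
    return vol, truth


def make_ratings(seed=0, n=40, spread=6):
    """Two correlated integer rating columns in 0..40 for agreement tests."""
    rng = np.random.default_rng(seed)
    base = rng.integers(10, 41 - spread, size=n)
    a = np.clip(base + rng.integers(-2, 3, size=n), 0, 40)
    b = np.clip(base + rng.integers(-2, 3, size=n), 0, 40)
    return a, b
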