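import numpy as np
import pytest
from hypothesis import settings

from cartseg.objectives import histogram_from_counts

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_condensed_histogram(seed: int, n_active=(12, 64), max_count=1000):
    """Random histogram with a limited number of active bins."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(256, dtype=np.int64)
    nb = int(rng.integers(*n_active))
    bins = rng.choice(256, nb, replace=False)
    counts[bins] = rng.integers(1, max_count, nb)
    return histogram_from_counts(counts)


@pytest.fixture
def condensed_histogram():
    return make_condensed_histogram(seed=11)


@pytest.fixture
def all_intensities_image():
    """16x16 image containing every intensity exactly once."""
    return np.arange(256, dtype=np.uint8).reshape(16, 16)
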