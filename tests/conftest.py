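import numpy as np
import pytest

from sparselogit import BinaryDataset, TwoByTwoTable


@pytest.fixture
def hydramnios():
    """Cohort 2x2: 1 death / 9 survivors exposed, 16 / 2,966 unexposed."""
    return TwoByTwoTable(a=1, b=9, c=16, d=2966)


@pytest.fixture
def vascular():
    """Case-control 2x2: 2/3 with vascular disease, 12/141 without."""
    return TwoByTwoTable(a=2, b=3, c=12, d=141)


@pytest.fixture
def rng():
    return np.random.default_rng(20230605)


def random_dataset(rng, n=30, k=2, weights=False):
    """Small random integer-covariate dataset with both outcome levels."""
    while True:
        X = rng.integers(0, 3, size=(n, k)).astype(float)
        y = rng.integers(0, 2, size=n).astype(float)
        if 0 < y.sum() < n:
            break
    w = rng.integers(1, 4, size=n).astype(float) if weights else None
    return BinaryDataset(y, X, w)
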