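import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lpifkl import SyntheticSpec, generate

SMALL_SPEC = SyntheticSpec(m=24, n=8, k_blocks=2, seq_len_range=(20, 40), seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A 24x8 two-block dataset, large enough for CV yet fast for every test."""
    return generate(SMALL_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_psd(rng, p, rank=None):
    X = rng.normal(size=(p, rank or p + 2))
    K = X @ X.T
    return K / np.abs(np.diag(K)).mean()


@pytest.fixture()
def random_psd_factory():
    return random_psd
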