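import numpy as np
import pytest
from hypothesis import settings

from isofactor.data import ObservedDataset, PriorConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset(rng):
    """Consistent n=10, q=2, r=4 dataset with a block-diagonal mask."""
    n, q, r = 10, 2, 4
    mask = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
    T = rng.normal(3, 1, (n, q))
    I = 5 + T + rng.standard_normal((n, q))
    Z = np.where(mask, 1.0, 0.0)
    P = np.abs(I @ Z + rng.standard_normal((n, r))) + 1.0
    A = np.array([1.0] * 5 + [0.0] * 5)
    return ObservedDataset(P=P, mask=mask, T=T, A=A)


@pytest.fixture
def default_prior():
    return PriorConfig()
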