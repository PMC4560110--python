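import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_spd(rng, j, jitter=0.5):
    """Random symmetric positive-definite matrix with unit-scale diagonal."""
    a = rng.standard_normal((j, j)) * jitter
    return a @ a.T + np.eye(j)
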