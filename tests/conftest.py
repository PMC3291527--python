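import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def unit_norm_dictionary(n: int, m: int, seed: int) -> np.ndarray:
    """Gaussian dictionary with unit-norm columns, for solver tests."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, m))
    return A / np.linalg.norm(A, axis=0)
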