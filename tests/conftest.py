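import numpy as np
import pytest


def orthonormal_design(n: int, p: int, rng) -> np.ndarray:
    """n x p design with X'X = n I (scaled orthonormal basis)."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
    return np.sqrt(n) * Q


@pytest.fixture
def rng():
    return np.random.default_rng(0)
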