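import numpy as np
import pytest


def random_instance(seed, n=10, m=20, lam=1.0):
    """Random genotype-like matrix in {0,1,2} with balanced-ish ±1 labels."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    y = rng.choice([-1.0, 1.0], size=m)
    if np.all(y == y[0]):  # avoid one-class degenerate draws
        y[0] = -y[0]
    return X, y, lam


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_instance():
    """The 1-feature / 2-example worked instance used throughout the docs."""
    X = np.array([[1.0, -1.0]])
    y = np.array([1.0, -1.0])
    return X, y, 1.0
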