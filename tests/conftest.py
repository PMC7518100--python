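import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor(rng):
    return rng.normal(size=(3, 4, 5, 6))


def low_multilinear_rank_tensor(rng, shape, ranks, scale=1.0):
    """Random tensor with exact multilinear rank ``ranks`` built as a random
    core expanded through orthonormal factors."""
    core = rng.normal(size=ranks) * scale
    t = core
    for ax, (dim, r) in enumerate(zip(shape, ranks)):
        q, _ = np.linalg.qr(rng.normal(size=(dim, r)))
        t = np.moveaxis(np.tensordot(q, t, axes=(1, ax)), 0, ax)
    return t


@pytest.fixture
def low_rank_tensor_factory(rng):
    def factory(shape=(4, 4, 4, 8), ranks=(2, 2, 2, 2), scale=1.0, seed=None):
        local = rng if seed is None else np.random.default_rng(seed)
        return low_multilinear_rank_tensor(local, shape, ranks, scale)

    return factory
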