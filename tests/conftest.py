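import numpy as np
import pytest

from rangeen import NoiseSpec, gen_noise


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def white_1000():
    """One seeded unit-variance white-noise signal of length 1000."""
    return gen_noise(NoiseSpec("white", 1000, 42))


@pytest.fixture(scope="session")
def small_signals():
    """A mixed bag of short random signals for oracle comparisons."""
    rng = np.random.default_rng(777)
    signals = []
    for _ in range(8):
        n = int(rng.integers(20, 51))
        kind = rng.integers(3)
        if kind == 0:
            x = rng.standard_normal(n)
        elif kind == 1:
            x = np.cumsum(rng.standard_normal(n))  # walk-like
        else:
            t = np.arange(n)
            x = np.sin(0.3 * t) + 0.3 * rng.standard_normal(n)
        signals.append(x)
    return signals
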