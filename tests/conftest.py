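import numpy as np
import pytest

from actipersist import PersistenceDiagram, Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_signal(rng, max_len=30, integer_prob=0.5):
    """Short random signal, half the time integer-valued to force ties."""
    n = int(rng.integers(0, max_len + 1))
    if rng.random() < integer_prob:
        values = rng.integers(0, 5, size=n).astype(float)
    else:
        values = rng.normal(size=n)
    return Signal(values)


def random_diagram(rng, max_points=4, scale=5.0):
    """Random small diagram with death >= birth."""
    r = int(rng.integers(0, max_points + 1))
    births = rng.uniform(0, scale, size=r)
    deaths = births + rng.uniform(0, scale, size=r)
    return PersistenceDiagram(births, deaths)
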