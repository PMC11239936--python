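import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_densities(rng, n, avoid_additive=True):
    """Density vector strictly inside (0,1); optionally nudged off sum=1."""
    g = rng.uniform(0.05, 0.95, size=n)
    if avoid_additive and abs(g.sum() - 1.0) < 1e-6:
        g = g * 1.1
        g = np.clip(g, 0.05, 0.95)
    return g
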