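import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def image_pair_factory(rng):
    """Seeded random uint8-valued image pairs on the 0-255 scale."""

    def make(shape=(16, 16), correlated=False):
        x = rng.uniform(0, 255, shape)
        if correlated:
            y = np.clip(x + rng.normal(0, 25, shape), 0, 255)
        else:
            y = rng.uniform(0, 255, shape)
        return x, y

    return make
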