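import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_box(rng, lo=0.0, hi=50.0, min_side=1.0, max_side=30.0):
    x1 = rng.uniform(lo, hi)
    y1 = rng.uniform(lo, hi)
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    return np.array([x1, y1, x1 + w, y1 + h])
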