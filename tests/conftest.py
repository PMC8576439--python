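import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def bright_pixel_image():
    """9x9 constant floor 10 with one bright pixel at the centre."""
    img = np.full((9, 9), 10.0)
    img[4, 4] = 60.0
    return img
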