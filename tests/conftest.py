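import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

from echotexture.ultrasound_io import ROIPatch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """A 32x32 patch of i.i.d. uniform 8-bit intensities."""
    return ROIPatch(pixels=rng.integers(0, 256, size=(32, 32)))


def make_patch(rng, h=16, w=16, levels=256):
    return ROIPatch(pixels=rng.integers(0, levels, size=(h, w)))
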