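import numpy as np
import pytest

from wormscatter import Image, WormMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_frame(rng):
    """Random 16-bit dark-field frame."""
    return Image(pixels=rng.integers(0, 4000, size=(64, 64)).astype(float),
                 bit_depth=16, modality="darkfield")


def make_mask(mask_array, label="worm_00"):
    return WormMask(mask=np.asarray(mask_array, dtype=bool), label=label,
                    source="auto_threshold", threshold_used=0.0)


@pytest.fixture
def mask_factory():
    return make_mask
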