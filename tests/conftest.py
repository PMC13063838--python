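import numpy as np
import pytest

from gliorad.preprocess import QuantizedVolume, VoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_random_volume(rng):
    """6x6x6 quantized volume with a random blob mask (both masks valid)."""
    levels = rng.integers(0, 8, size=(6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.7
    mask[2:4, 2:4, 2:4] = True  # guarantee nonempty, connected center
    return (
        QuantizedVolume(levels=levels.astype(np.int16), channel="T2", source_range=(0, 7)),
        VoiMask(mask, label="core"),
    )


def make_quantized(levels, channel="T2"):
    levels = np.asarray(levels, dtype=np.int16)
    return QuantizedVolume(levels=levels, channel=channel,
                           source_range=(0, int(levels.max(initial=0))))
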