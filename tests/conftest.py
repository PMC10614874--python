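import numpy as np
import pytest

from hocoord.markspace import SpikeRaster, to_marked


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_raster(rng):
    """4 neurons x 300 bins of moderately active independent spiking."""
    data = (rng.random((4, 300)) < 0.12).astype(np.uint8)
    return SpikeRaster(data)


@pytest.fixture
def small_marked(small_raster):
    return to_marked(small_raster)
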