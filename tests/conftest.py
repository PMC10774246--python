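import numpy as np
import pytest
from scipy import ndimage

import spectseg as ss
from spectseg.simulate import FWHM_TO_SIGMA

SMALL_GRID = (64, 64, 64)


@pytest.fixture(scope="session")
def phantom20_small():
    """20 ml phantom with a 10 % hotspot on a 64^3 grid (fast to simulate)."""
    return ss.place_hotspot(ss.build_phantom(20, 4.42, SMALL_GRID))


@pytest.fixture(scope="session")
def phantom35_full():
    """35 ml phantom with hotspot on the default 128^3 grid."""
    return ss.place_hotspot(ss.build_phantom(35))


@pytest.fixture(scope="session")
def noiseless35(phantom35_full):
    """Noise-free system-resolution-blurred homogeneous 35 ml image."""
    act = ss.compose_activity(phantom35_full, ss.CaseSpec(35, 0.0, 1.0))
    blurred = ndimage.gaussian_filter(act.values, 7.5 * FWHM_TO_SIGMA / 4.42)
    return ss.ReconVolume(values=blurred, voxel_size=4.42, provenance="surrogate")


@pytest.fixture(scope="session")
def quantized35(noiseless35, phantom35_full):
    rois = ss.derive_rois(noiseless35, truth=phantom35_full)
    return ss.preprocess_volume(noiseless35, rois)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
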