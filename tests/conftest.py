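import numpy as np
import pytest

from voxel2pixel.rf_transport import Canvas, RFCenterTable
from voxel2pixel.synthetic_data import make_retinotopy, make_toy_video, simulate_voxels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_canvas():
    return Canvas(8, 8)


@pytest.fixture
def rf_table(rng, small_canvas):
    n = 10
    return RFCenterTable("V1",
                         rng.uniform(0, small_canvas.width, n),
                         rng.uniform(0, small_canvas.height, n))


@pytest.fixture
def canvas16():
    return Canvas(16, 16)


@pytest.fixture
def toy_session(canvas16):
    """Small noiseless one-voxel-per-pixel session (3 pseudo-ROIs, lag 5)."""
    video = make_toy_video(40, canvas16, seed=7)
    ret = make_retinotopy(canvas16.n_pixels, canvas16, jitter_sds=(0, 0, 0), seed=7)
    return simulate_voxels(video, ret, lag_tr=5, noise_sd=0.0, seed=7)
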