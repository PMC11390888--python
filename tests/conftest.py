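import numpy as np
import pytest

from retinacode.retina_simulator import build_mosaic, sample_ground_truth_params

IMAGE_SIZE = 32
PIXEL_PITCH = 11.0
FIELD_UM = IMAGE_SIZE * PIXEL_PITCH  # 352 um


@pytest.fixture(scope="session")
def mosaic():
    return build_mosaic((FIELD_UM, FIELD_UM), jitter_fraction=0.1, seed=0)


@pytest.fixture(scope="session")
def encoder(mosaic):
    return sample_ground_truth_params(
        mosaic, seed=1, pixel_pitch_um=PIXEL_PITCH,
        image_shape=(IMAGE_SIZE, IMAGE_SIZE),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
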