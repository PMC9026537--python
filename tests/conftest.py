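import numpy as np
import pytest

from ccflow import EnFaceImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240411)


def make_image(pixels, pitch=6.6, modality="compensated", eye_id=""):
    return EnFaceImage(
        pixels=np.asarray(pixels, dtype=np.float64),
        pixel_pitch_um=pitch,
        modality=modality,
        eye_id=eye_id,
    )


@pytest.fixture
def image_factory():
    return make_image
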