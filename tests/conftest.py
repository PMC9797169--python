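import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from radnoise import NoiseModel, Radiograph, generate_uniform_pair

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def white_noise_pair():
    """512x512 pair of pure white Gaussian noise, SD 10, mean 1000."""
    nm = NoiseModel(gain=0.0, electronic_sd=10.0)
    return generate_uniform_pair((512, 512), 1000.0, 1.0, 1.0, nm, seed=11)


@pytest.fixture
def white_noise_image(white_noise_pair):
    return white_noise_pair[0]


def make_radiograph(pixels, pitch=0.15, mas=1.0):
    return Radiograph(np.asarray(pixels, dtype=float), pixel_pitch=pitch, mas=mas)
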