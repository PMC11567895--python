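import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from chromring.config import preset_config
from chromring.synthetic import generate_nucleus_scene


#: noiseless, blur-free rendering overrides
NOISELESS = dict(photon_scale=float("inf"), read_noise_sd=0.0,
                 psf_sigma_xy=0.0, psf_sigma_z=0.0)

#: small nuclei for fast tests (2 µm radius, nucleolus scaled to match)
SMALL = dict(nucleus_radius=2.0, nucleolus_sigmas=(0.4, 0.4, 0.4))


@pytest.fixture(scope="session")
def fed_scene_clean():
    """Noiseless, blur-free fed-preset scene at full size."""
    return generate_nucleus_scene(preset_config("fed", seed=0, **NOISELESS))


@pytest.fixture(scope="session")
def fasted_scene_clean():
    return generate_nucleus_scene(preset_config("fasted", seed=0, **NOISELESS))


@pytest.fixture(scope="session")
def fasted_scene_noisy():
    """Fasted-preset scene at the default noise level."""
    return generate_nucleus_scene(preset_config("fasted", seed=3))


@pytest.fixture(scope="session")
def small_fed_scene():
    return generate_nucleus_scene(preset_config("fed", seed=1, **SMALL))


def truth_nucleolus_mask2d(scene):
    """Half-maximum disc of the true nucleolar Gaussian at the central plane."""
    _, cy, cx = scene.truth.nucleolus_centre
    r = np.sqrt(2 * np.log(2)) * scene.truth.nucleolus_sigmas_vox[1]
    yy, xx = np.mgrid[0 : scene.mask2d.shape[0], 0 : scene.mask2d.shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
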