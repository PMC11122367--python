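import numpy as np
import pytest

from octaquant import SceneParams, generate_scene

#: small-grid study conditions used across tests: same 5.13 um/px pitch as
#: the nominal 3 mm / 585 px scan, scaled down for speed
SMALL = dict(shape=(128, 128), extent_mm=(0.656, 0.656), faz_radius_mm=0.0604)
MEDIUM = dict(shape=(256, 256), extent_mm=(1.313, 1.313), faz_radius_mm=0.1208)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, unshaded synthetic tree scene with ground truth."""
    params = SceneParams(**SMALL, target_vad=0.3, noise=("none",), shading=0.0)
    return generate_scene(params, seed=11)


@pytest.fixture(scope="session")
def default_scene():
    """Scene under the default (noisy, shaded) rendering conditions."""
    params = SceneParams(**SMALL, target_vad=0.3)
    return generate_scene(params, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
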