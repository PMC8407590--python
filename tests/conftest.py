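import numpy as np
import pytest

import ssdkit as sk

SCENE_SEED = 0


@pytest.fixture(scope="session")
def default_scene():
    """Full-length default synthetic scene (180 s, 20 channels, seed 0)."""
    rec, truth = sk.simulate_recording(duration=180.0, seed=SCENE_SEED)
    return rec, truth


@pytest.fixture(scope="session")
def alpha_band():
    return sk.make_band(10.0)


@pytest.fixture(scope="session")
def fitted_scene(default_scene, alpha_band):
    """SSD model fitted to the default scene in the alpha band."""
    rec, truth = default_scene
    model = sk.fit_ssd(rec, alpha_band)
    return rec, truth, model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, k, scale=1.0):
    """Random symmetric positive-definite matrix."""
    a = rng.standard_normal((k, k))
    return scale * (a @ a.T + k * np.eye(k))
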