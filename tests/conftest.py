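import numpy as np
import pytest

from calimo import registration as reg
from calimo import synthetic as syn


@pytest.fixture(scope="session")
def blob_scene():
    """Small multi-blob soma scene (64x64) used across registration tests."""
    spec = syn.SceneSpec(kind="soma", size=(64, 64), n_structures=4,
                         radius=2.0, amplitude=150.0, background=20.0,
                         noise_sd=0.0, seed=1)
    return syn.make_scene(spec)


@pytest.fixture(scope="session")
def blob_template(blob_scene):
    return reg.Template.from_image(blob_scene.image)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
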