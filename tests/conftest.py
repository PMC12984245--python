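import numpy as np
import pytest

from cortexfuse.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def scene():
    """One deterministic desk-scale scene shared across tests.

    RGB at 4x the HSI grid keeps the pseudo-label tests fast while preserving
    the high-resolution-RGB / low-resolution-HSI relationship.
    """
    cfg = SceneConfig(seed=0, rgb_size=(868, 1636), n_vessels=7)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def scene_small_rgb():
    cfg = SceneConfig(seed=3, rgb_size=(434, 818), n_vessels=6)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
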