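import numpy as np
import pytest

from kaizen import EngineConfig, OraclePredictor, SceneParams, generate_scene

TOY_PATCH = 32


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def clean_scene():
    """Noiseless 8-cell scene with non-overlapping cells."""
    return generate_scene(SceneParams(n_cells=8, background_noise_sd=0.0, seed=3))


@pytest.fixture
def noisy_scene():
    return generate_scene(SceneParams(n_cells=8, background_noise_sd=0.02, seed=3))


@pytest.fixture
def oracle(clean_scene):
    return OraclePredictor(clean_scene, TOY_PATCH)


@pytest.fixture
def engine_config():
    return EngineConfig(patch_size=TOY_PATCH)
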