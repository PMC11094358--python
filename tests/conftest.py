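import numpy as np
import pytest

from earcount import ModelConfig, SceneConfig, build_model, generate_scene


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 level-1 scene."""
    return generate_scene(SceneConfig(image_size=(128, 128), level=1, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
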