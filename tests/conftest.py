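import numpy as np
import pytest

from fruitshot import SceneConfig, generate_scene
from fruitshot.synthgen import cpu_scene_config


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 208-px synthetic scene with exact labels."""
    return generate_scene(cpu_scene_config(), seed=42)


@pytest.fixture(scope="session")
def tiny_detector():
    """An untrained 13-grid detector for shape/contract tests."""
    from fruitshot import build, tiny_spec

    return build(tiny_spec(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
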