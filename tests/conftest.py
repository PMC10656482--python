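import numpy as np
import pytest

from rseikit.datasets import caohai_area_tables
from rseikit.synth import default_scene_spec, generate_scene, uniform_landuse
from rseikit.types import GRASSLAND


@pytest.fixture(scope="session")
def caohai_tables():
    return caohai_area_tables()


@pytest.fixture(scope="session")
def gradient_scene():
    """Single-class scene over a left-to-right ecological ramp (seed 7)."""
    spec = default_scene_spec((200, 200))
    lu = uniform_landuse(GRASSLAND, (200, 200))
    scene, g = generate_scene(lu, spec, seed=7)
    return scene, g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
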