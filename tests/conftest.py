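import numpy as np
import pytest

from aquaveg import GridGeoref, ReflectanceScene, SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_scene(rng):
    """32x32 random-reflectance TM scene (values in [0, 0.5])."""
    bands = rng.uniform(0.0, 0.5, size=(6, 32, 32))
    return ReflectanceScene(bands=bands, sensor_id="TM")


@pytest.fixture
def quadrant_scene():
    """Noiseless default four-quadrant scene with its ground truth."""
    return generate_scene(SceneSpec(width=32, height=32, noise_sd=0.0, seed=0))


# Table printed by the study's accuracy assessment: rows = reference
# (FEAV, SAV, AB, OW), columns = predicted.
TABLE1_COUNTS = [
    [10, 0, 0, 0],
    [88, 775, 17, 0],
    [0, 0, 160, 0],
    [11, 88, 6, 2036],
]
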