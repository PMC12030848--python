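import numpy as np
import pytest

from lomlprnn.spectral_io import Scene
from lomlprnn.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene(rng):
    """A 4-band 10x12 scene with deterministic values."""
    values = rng.uniform(0.0, 0.5, size=(4, 10, 12))
    return Scene(values, pixel_size=10.0, band_names=["B", "G", "R", "NIR"],
                 date_tag="t0")


@pytest.fixture(scope="session")
def default_scene_pair():
    """A 7-class 12-band 64x64 scene plus its label map (session-cached)."""
    return generate_scene(SceneSpec(height=64, width=64, seed=7))
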