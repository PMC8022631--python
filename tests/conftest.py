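import numpy as np
import pytest

from drhn.hierarchy import build_default_tree
from drhn.synthetic import SceneParams, SubjectParams


@pytest.fixture(scope="session")
def tree():
    return build_default_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def subject():
    return SubjectParams(
        torso_length=21.0, head_radius=5.0, shoulder_width=8.0, seat_height=7.0
    )


@pytest.fixture(scope="session")
def scene():
    return SceneParams(image_size=(48, 64))


@pytest.fixture(scope="session")
def quiet_scene():
    """Noise-free depth sensor for deterministic geometry assertions."""
    return SceneParams(image_size=(48, 64), depth_noise_sd=0.0, edge_dropout_p=0.0)
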