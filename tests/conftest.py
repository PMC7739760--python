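import numpy as np
import pytest

from mocapkit.synthetic_scene import SceneConfig, generate_skeleton_motion, make_camera_ring


@pytest.fixture(scope="session")
def walk_config():
    """Short walking trial at study-like 1K settings (5 cameras,
    1920x1080, 120 Hz, 2 px noise)."""
    return SceneConfig(task="walk", condition="1K", duration=2.0, seed=11)


@pytest.fixture(scope="session")
def camera_ring(walk_config):
    """Five-camera ring plus its 12 surveyed control points."""
    return make_camera_ring(walk_config)


@pytest.fixture(scope="session")
def walk_truth(walk_config):
    return generate_skeleton_motion(walk_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
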