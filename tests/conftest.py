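import numpy as np
import pytest

from selfee.model import NetworkConfig, SelfeeNet
from selfee.preprocess import FrameStore
from selfee.synthetic import default_two_agent_script, generate_scene_video


@pytest.fixture(scope="session")
def tiny_net_cfg() -> NetworkConfig:
    return NetworkConfig(backbone="small", proj_dim=32, pred_hidden=8,
                         disc_dim=16, small_width=4)


@pytest.fixture(scope="session")
def tiny_net(tiny_net_cfg) -> SelfeeNet:
    return SelfeeNet(tiny_net_cfg, seed=0)


@pytest.fixture(scope="session")
def small_scene():
    """A short 3-state two-agent scene at test scale."""
    script = default_two_agent_script(duration=80, seed=11, arena_size=48)
    return generate_scene_video(script, arena=(48, 48), semi_axes=(4.0, 1.8))


@pytest.fixture(scope="session")
def small_store(small_scene) -> FrameStore:
    return FrameStore.from_array(small_scene.frames, video_id="scene")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
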