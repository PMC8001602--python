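import numpy as np
import pytest

from nglseg.synthdata import SyntheticSceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene_cfg():
    """A 128x128 scene config cheap enough for per-test generation."""
    return SyntheticSceneConfig(height=128, width=128, n_target_clusters=3,
                                cluster_radius_px=(3, 14), seed=42)


@pytest.fixture(scope="session")
def small_scene(small_scene_cfg):
    return generate_scene(small_scene_cfg)
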