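import tempfile

import numpy as np
import pytest
from hypothesis import configuration, settings

import lidarpheno as lp

# keep hypothesis caches out of the repository
configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hyp-"))
settings.register_profile("ci", database=None, derandomize=True,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_scene():
    """A 30-plant scene with terrain, occlusion and outliers, shared by
    the pipeline-recovery and segmentation tests (generation ~2 s)."""
    specs = lp.random_plant_specs(30, seed=5)
    scene_spec = lp.SceneSpec(
        n_varieties=10, plants_per_variety=3, terrain_amplitude=0.05,
        sensor_point_spacing=0.004, outlier_rate=0.005,
        occlusion_rate=0.1, seed=11)
    return lp.generate_scene(scene_spec, specs)


@pytest.fixture(scope="session")
def clean_scene():
    """Small noise-free scene over sinusoidal terrain (for ground
    classification and normalization truth checks)."""
    specs = lp.random_plant_specs(12, seed=3)
    scene_spec = lp.SceneSpec(
        n_varieties=4, plants_per_variety=3, terrain_amplitude=0.05,
        sensor_point_spacing=0.005, seed=2)
    return lp.generate_scene(scene_spec, specs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
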