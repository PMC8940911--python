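import numpy as np
import pytest

from somatrace import synthetic_data as sd


@pytest.fixture(scope="session")
def small_scene():
    """10 well-separated somata, 128x128, 60 frames, noiseless, with spikes."""
    cfg = sd.default_scene_config(
        n_cells=10, fov_shape=(128, 128), n_frames=60, noise_sigma=0.0
    )
    return sd.generate_scene(cfg, seed=11)


@pytest.fixture(scope="session")
def small_movie(small_scene):
    return sd.render_movie(small_scene)


@pytest.fixture(scope="session")
def static_scene():
    """Static fixture: no spikes, no noise, no neuropil — frames identical."""
    cfg = sd.default_scene_config(
        n_cells=8,
        fov_shape=(128, 128),
        n_frames=20,
        noise_sigma=0.0,
        spike_rate=0.0,
    )
    return sd.generate_scene(cfg, seed=7)


@pytest.fixture(scope="session")
def static_movie(static_scene):
    return sd.render_movie(static_scene)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
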