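import numpy as np
import pytest

from imequant import simcam


@pytest.fixture()
def small_camera() -> simcam.CameraModel:
    """A 64x64 camera with a seeded dark map, fast enough for unit tests."""
    dark = simcam.sample_dark_current_map(64, 64, mean_offset=100.0, pixel_sd=5.0, seed=7)
    return simcam.CameraModel(dark_map=dark)


@pytest.fixture()
def small_phantom_params() -> dict:
    """Worm phantom parameters that fit a 64x64 frame."""
    return dict(rows=64, cols=64, channel_width_px=16, tube_radius_px=4,
                worm_radius_px=4.6, chamber_depth_px=6.2)


@pytest.fixture()
def disk_camera() -> simcam.CameraModel:
    dark = simcam.sample_dark_current_map(32, 32, mean_offset=100.0, pixel_sd=5.0, seed=3)
    return simcam.CameraModel(dark_map=dark)


def make_uniform_phantom(rows: int = 32, cols: int = 32, radius: int = 10) -> simcam.WormPhantom:
    return simcam.render_disk_phantom(rows, cols, radius)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
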