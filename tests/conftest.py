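import numpy as np
import pytest

import lockinsim as L


@pytest.fixture(scope="session")
def opt64():
    return L.build_optical_model(488.0, 1.49, 65.0, (64, 64))


@pytest.fixture(scope="session")
def opt128():
    return L.build_optical_model(488.0, 1.49, 65.0, (128, 128))


@pytest.fixture(scope="session")
def opt256():
    return L.build_optical_model(488.0, 1.49, 65.0, (256, 256))


@pytest.fixture(scope="session")
def illum128(opt128):
    return L.default_illumination(opt128, m=0.9)


@pytest.fixture(scope="session")
def illum256(opt256):
    return L.default_illumination(opt256, m=0.9)


@pytest.fixture(scope="session")
def filament_sim(opt128, illum128):
    """Noiseless 128x128 crossed-filament acquisition with known parameters."""
    scene = L.make_scene("crossed_filaments", {"n": 8}, seed=1, shape=(128, 128))
    recipe = L.SimulationRecipe(optical=opt128, illum=illum128, noise_sd=0.0, seed=1)
    raw, widefield = L.render_sim_raw(scene, recipe)
    return scene, raw, widefield


@pytest.fixture(scope="session")
def bead_sim(opt256, illum256):
    """Noiseless 256x256 100-nm bead acquisition with known parameters."""
    scene = L.make_scene("beads", {"n": 25, "diameter_nm": 100.0}, seed=3, shape=(256, 256))
    recipe = L.SimulationRecipe(optical=opt256, illum=illum256, noise_sd=0.0, seed=3)
    raw, widefield = L.render_sim_raw(scene, recipe)
    return scene, raw, widefield


def line_image(angle_deg, shape=(96, 96), width_px=1.0):
    """Single straight fiber through the image centre at a known angle."""
    from lockinsim.simulate import _draw_segment

    img = np.zeros(shape)
    c = (shape[0] - 1) / 2.0
    a = np.deg2rad(angle_deg)
    r = 0.45 * shape[0]
    _draw_segment(
        img,
        (c - r * np.sin(a), c - r * np.cos(a)),
        (c + r * np.sin(a), c + r * np.cos(a)),
        width_px,
    )
    return img


def angular_error_deg(theta, truth):
    """Axial angular error |theta - truth| folded into [0, 90]."""
    return np.abs(((np.asarray(theta) - truth + 90.0) % 180.0) - 90.0)
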