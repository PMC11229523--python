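import numpy as np
import pytest

from fruitmorph import morphometry, synthfruit


@pytest.fixture
def calibration():
    """0.25 mm per pixel desk-scale calibration (self-consistent area ratio)."""
    return morphometry.CameraCalibration(mm_per_px=0.25, mm2_per_px=0.0625)


@pytest.fixture
def ellipse_mask():
    """Axis-aligned rendered ellipse with semi-axes (80, 50) px plus truth."""
    spec = synthfruit.FruitImageSpec(semi_axes_px=(80.0, 50.0), pose_deg=0.0)
    return synthfruit.render_binary_ellipse(spec)


@pytest.fixture
def fruit_photo():
    """Prickly, shadowed, salt-noised fruit photograph with ground truth."""
    spec = synthfruit.FruitImageSpec(
        semi_axes_px=(80.0, 50.0), pose_deg=25.0, salt_rate=0.0005, seed=3
    )
    return synthfruit.render_fruit_photo(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240701)
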