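import numpy as np
import pytest
from scipy.ndimage import convolve

from lsamorph import CurveSpec, generate_curve


def endpoint_count(raster: np.ndarray) -> int:
    """Independent endpoint oracle: foreground pixels with exactly one
    8-neighbor."""
    raster = raster.astype(int)
    neighbors = convolve(raster, np.ones((3, 3), dtype=int),
                         mode="constant") - raster
    return int(((neighbors == 1) & (raster > 0)).sum())


@pytest.fixture
def straight_curve():
    curve, truth = generate_curve(CurveSpec("straight", chord_length=10.0,
                                            sample_count=101))
    return curve, truth


@pytest.fixture
def semicircle():
    curve, truth = generate_curve(CurveSpec(
        "circular_arc", chord_length=2.0, sample_count=400,
        parameters={"arc_angle": np.pi}))
    return curve, truth


@pytest.fixture
def sine_curve():
    """y = sin(x) on [0, 2*pi]: arc 7.6404, DM 1.2160, two critical points."""
    curve, truth = generate_curve(CurveSpec(
        "sinusoid", chord_length=2 * np.pi, sample_count=600,
        parameters={"amplitude": 1.0, "n_half": 2}))
    return curve, truth
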