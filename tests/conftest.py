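import numpy as np
import pytest

from ciliametrics.calibration import ImageCalibration


@pytest.fixture
def streak_cal() -> ImageCalibration:
    """1 µm/px, 1-s exposure: the long-exposure swimming assay geometry."""
    return ImageCalibration(um_per_px=1.0, exposure_s=1.0)


@pytest.fixture
def video_cal() -> ImageCalibration:
    """0.5 µm/px at 1000 fps: the high-speed bright-field geometry."""
    return ImageCalibration(um_per_px=0.5, fps=1000.0)


@pytest.fixture
def tirf_cal() -> ImageCalibration:
    """0.1 µm/px at 10 fps: the TIRF time-lapse geometry."""
    return ImageCalibration(um_per_px=0.1, fps=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
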