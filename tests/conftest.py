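import numpy as np
import pytest

from ribbontrack import GroundTruthScene, ImagingParams, PsfCalibration


@pytest.fixture
def params_sim():
    """Default imaging parameters, both channels sampled every record."""
    return ImagingParams(channel_scheme="simultaneous")


@pytest.fixture
def params_alt():
    """Default imaging parameters with line-alternating channels."""
    return ImagingParams(channel_scheme="alternate_lines")


@pytest.fixture
def psf():
    return PsfCalibration(sigma=110.0, source="configured")


@pytest.fixture
def scene_template():
    return GroundTruthScene()


@pytest.fixture
def x_nm():
    """Pixel-center coordinates for a 48-pixel, 40-nm/px scan line."""
    return (np.arange(48) + 0.5) * 40.0
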