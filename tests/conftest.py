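import numpy as np
import pytest

from gaze3.data_io import Fixation, Scanpath, ScanpathSet, ScreenGeometry


@pytest.fixture
def geometry():
    return ScreenGeometry(pixels_per_dva=1.0)


@pytest.fixture
def tiny_scanpath():
    """Forced central start plus three free fixations on a 32x32 image."""
    return Scanpath("img000", "s00", [
        Fixation(15.0, 15.0, forced=True),
        Fixation(10.0, 20.0),
        Fixation(25.0, 5.0),
        Fixation(12.0, 12.0),
    ])


@pytest.fixture
def tiny_set(tiny_scanpath, geometry):
    other = Scanpath("img000", "s01", [
        Fixation(15.0, 15.0, forced=True),
        Fixation(4.0, 4.0),
        Fixation(28.0, 28.0),
    ])
    return ScanpathSet(
        stimuli={"img000": (32, 32, None)},
        scanpaths=[tiny_scanpath, other],
        geometry=geometry,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
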