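import numpy as np
import pytest

from gamutkit import colorimetry as cm


@pytest.fixture(scope="session")
def d65():
    return cm.load_d65()


@pytest.fixture(scope="session")
def cmf1964():
    return cm.load_cmf_1964()


@pytest.fixture(scope="session")
def d65_coarse():
    """5-nm working grid: 64 zonotope generators, cheap volume sums."""
    return cm.load_d65(grid=(380.0, 700.0, 5.0))


@pytest.fixture(scope="session")
def cmf1964_coarse():
    return cm.load_cmf_1964(grid=(380.0, 700.0, 5.0))


@pytest.fixture(scope="session")
def boxcar_tables():
    """Unit illuminant with three disjoint boxcar CMFs on thirds of [0, 90].

    Each boxcar is zero on the transition intervals around the nominal
    boundaries 30 and 60, so the band tristimulus matrix at cuts (30, 60) is
    exactly diagonal with entries (29.5, 29.0, 29.5) and the object-color
    solid degenerates to the spanned box.
    """
    wl = np.arange(91, dtype=float)
    ill = cm.SpectralTable(wl, np.ones(91))
    vals = np.zeros((91, 3))
    vals[0:30, 0] = 1.0  # nonzero at nodes 0..29, ramp dies inside [29, 30]
    vals[31:60, 1] = 1.0
    vals[61:91, 2] = 1.0
    return ill, cm.SpectralTable(wl, vals), np.array([29.5, 29.0, 29.5])
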