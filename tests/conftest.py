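import numpy as np
import pytest

from pmfpath import LandscapeSpec


@pytest.fixture
def harmonic_1d():
    return LandscapeSpec("harmonic", {"stiffness": 10.0},
                         domain=((-1.5, 1.5),), axis_names=("x",))


@pytest.fixture
def flat_1d():
    return LandscapeSpec("harmonic", {"stiffness": 0.0},
                         domain=((-2.0, 2.0),), axis_names=("x",))


@pytest.fixture
def harmonic_2d():
    return LandscapeSpec("harmonic", {"stiffness": (1.0, 20.0), "center": (0.0, 0.0)},
                         domain=((-2.0, 2.0), (-2.0, 2.0)), axis_names=("x", "y"))


@pytest.fixture
def double_well():
    return LandscapeSpec("double_well_1d", {"h": 5.0, "a": 1.0})


@pytest.fixture
def double_well_2d():
    return LandscapeSpec("double_well_1d", {"h": 5.0, "a": 1.0, "ortho_stiffness": 2.0})


@pytest.fixture
def two_basin():
    return LandscapeSpec("two_basin_2d")


@pytest.fixture
def step1_surface():
    return LandscapeSpec("psp_step1_like")


@pytest.fixture
def step2_surface():
    return LandscapeSpec("psp_step2_like")


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
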