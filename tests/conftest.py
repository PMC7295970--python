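"""Shared fixtures: synthetic frames are generated once per session."""

import numpy as np
import pytest

from nanocav import detect_cavity, make_fluid_with_cavity


@pytest.fixture(scope="session")
def carved_frame():
    """Fluid box (120 Å)³ at 1.02 g/cm³ with a carved 50 Å spherical void."""
    frame, truth = make_fluid_with_cavity([120, 120, 120], cavity_radius=50.0, seed=1)
    return frame, truth


@pytest.fixture(scope="session")
def carved_field(carved_frame):
    """Default-parameter cavity detection of the carved frame."""
    frame, truth = carved_frame
    return detect_cavity(frame), truth


@pytest.fixture(scope="session")
def homogeneous_frame():
    """Homogeneous fluid box (80 Å)³ at 1.02 g/cm³, no cavity."""
    frame, truth = make_fluid_with_cavity([80, 80, 80], cavity_radius=0.0, seed=2)
    return frame, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
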