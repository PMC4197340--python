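"""Shared fixtures: phantom bones, camera, and rendered synthetic trials.

Everything is generated programmatically and seeded; session scope keeps
the rendering cost paid once.
"""

import numpy as np
import pytest

from tarsokin.registration import edge_map
from tarsokin.synthetic import (condition_script, default_camera,
                                make_phantom, make_trial)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def camera():
    return default_camera()


@pytest.fixture(scope="session")
def barefoot_script():
    return condition_script("barefoot")


@pytest.fixture(scope="session")
def landing_trial(phantom, barefoot_script):
    """Low-noise rendered landing: 15 post-contact frames at 60 Hz."""
    return make_trial(phantom, barefoot_script, seed=1, image_noise=0.01,
                      n_before=0, n_after=14)


@pytest.fixture(scope="session")
def full_window_trial(phantom, barefoot_script):
    """Unrendered trial covering the full −33…+250 ms analysis window."""
    return make_trial(phantom, barefoot_script, seed=2, render=False)


@pytest.fixture(scope="session")
def contact_frame(landing_trial):
    """The toe-contact frame image and its edge distance field."""
    img = landing_trial.sequence.frames[0]
    return img, edge_map(img, upsample=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
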