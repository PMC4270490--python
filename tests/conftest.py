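"""Shared fixtures: presets and canonical synthetic fibers."""

import numpy as np
import pytest

from myonuc import synthetic as sy

POSITION_UPP = 0.2  # µm/px, whole-muscle imagery
PROFILE_UPP = 0.05  # µm/px, high-magnification profile imagery


@pytest.fixture(scope="session")
def presets():
    return sy.load_presets()


@pytest.fixture(scope="session")
def control_preset(presets):
    return presets["control"]


@pytest.fixture(scope="session")
def noiseless(presets):
    """Factory: preset by name with the noise turned off."""

    def _get(name):
        return presets[name].replace(noise={"gaussian_sd": 0.0})

    return _get


@pytest.fixture(scope="session")
def straight_fiber():
    return sy.make_fiber(40.0, 6.0, POSITION_UPP, 0.0, seed=1)


@pytest.fixture(scope="session")
def control_scene(straight_fiber, noiseless):
    """Fiber + nuclei + noiseless rendered image + truth, control preset."""
    preset = noiseless("control")
    nuclei = sy.place_nuclei(straight_fiber, preset, seed=1)
    image, truth = sy.render_channels(straight_fiber, nuclei, preset, seed=1)
    return straight_fiber, nuclei, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
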