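"""Shared fixtures: one default holey-carbon scene engaged noiselessly and
noisily at the working defocus, reused across test modules (engagement is the
expensive step)."""

import numpy as np
import pytest

from nanolock.control import engage
from nanolock.estimation import AXES, AxisStackConfig
from nanolock.simulator import NoiseModel, VirtualMicroscope, VirtualScene

WORKING_Z = 2000.0  # nm; axial sensitivity requires defocus


@pytest.fixture(scope="session")
def scene():
    return VirtualScene(seed=1)


@pytest.fixture(scope="session")
def stack_cfgs():
    return {ax: AxisStackConfig(axis=ax) for ax in AXES}


@pytest.fixture(scope="session")
def engaged_noiseless(scene, stack_cfgs):
    """(stacks, setpoint) from a noiseless, drift-free engagement."""
    mic = VirtualMicroscope(scene, noise=None, start_position_nm=(0, 0, WORKING_Z), seed=3)
    stacks, setpoint, _ = engage(mic, stack_cfgs)
    return stacks, setpoint


@pytest.fixture(scope="session")
def engaged_noisy(scene, stack_cfgs):
    """(stacks, setpoint, noise_model) engaged with shot/read noise on."""
    noise = NoiseModel(seed=11)
    mic = VirtualMicroscope(
        scene, noise=noise, start_position_nm=(0, 0, WORKING_Z), seed=3
    )
    stacks, setpoint, _ = engage(mic, stack_cfgs)
    return stacks, setpoint, noise


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
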