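"""Shared fixtures: deterministic phantoms and setups reused across tests."""

import numpy as np
import pytest

from ktpulse.fieldsim import (PhantomConfig, SafetyConfig, generate_phantom,
                              generate_safety_model)
from ktpulse.sta_core import SequenceTiming, TransmitSetup


@pytest.fixture(scope="session")
def kt_timing() -> SequenceTiming:
    """Default excitation block: 5 x 200 us subpulses, 100 us blips,
    TR = 8 ms."""
    return SequenceTiming()


@pytest.fixture(scope="session")
def phantom():
    """Default 32^3 head phantom, fixed seed."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def setup32(phantom):
    return phantom[0]


@pytest.fixture(scope="session")
def tissue32(phantom):
    return phantom[1]


@pytest.fixture(scope="session")
def safety32(setup32):
    return generate_safety_model(SafetyConfig(seed=2), setup32)


@pytest.fixture(scope="session")
def small_phantom():
    """16^3 phantom for optimization-heavy tests."""
    return generate_phantom(PhantomConfig(seed=5, grid_shape=(16, 16, 16)))


@pytest.fixture(scope="session")
def small_safety(small_phantom):
    return generate_safety_model(SafetyConfig(seed=6), small_phantom[0])


def uniform_setup(n_channels: int = 1, n_voxels: int = 1,
                  sens: float = 1.0) -> TransmitSetup:
    """Spatially uniform on-resonance setup (sensitivity in uT/V)."""
    coords = np.zeros((n_voxels, 3))
    if n_voxels > 1:
        coords[:, 0] = np.linspace(-0.05, 0.05, n_voxels)
    s = np.full((n_channels, n_voxels), sens, complex)
    return TransmitSetup(voxel_coords=coords, sensitivities=s,
                         delta_b0=np.zeros(n_voxels),
                         mask=np.ones(n_voxels, bool))


@pytest.fixture
def single_channel_setup():
    """One channel, one on-resonance voxel, s = 1 uT/V."""
    return uniform_setup()
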