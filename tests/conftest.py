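import numpy as np
import pytest

from percspace import (EyeMovementProfile, NetworkConfig, PlasmaProfile,
                       TorusLattice, psilocybin)


@pytest.fixture
def zero_plasma():
    return PlasmaProfile(np.array([0.0, 1e4]), np.array([0.0, 0.0]))


@pytest.fixture
def psilocybin_pk():
    return psilocybin()


@pytest.fixture
def lattice():
    return TorusLattice()


@pytest.fixture
def net_cfg():
    return NetworkConfig(seed=1)


@pytest.fixture
def constant_eyes():
    return EyeMovementProfile(mode="constant", velocity=(0.01, 0.01))
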