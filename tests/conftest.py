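import numpy as np
import pytest

from trapsurvey import (LEEK_MOTH, MEDFLY, DispersalParams, SimConfig,
                        TrapLayout, build_square_grid)


@pytest.fixture(scope="session")
def leek_layout():
    return build_square_grid(LEEK_MOTH.standard_grid)


@pytest.fixture(scope="session")
def medfly_layout():
    return build_square_grid(MEDFLY.standard_grid)


@pytest.fixture
def single_trap_layout():
    """One trap 15 m east of the origin with 1/λ = 10 m."""
    return TrapLayout(np.array([15.0]), np.array([0.0]), np.array([10.0]))


@pytest.fixture
def fast_cfg():
    """Small Monte-Carlo configuration for property tests."""
    return SimConfig(iterations=40, duration_days=10, n_insects=20, seed=11)


@pytest.fixture
def leek_disp():
    return DispersalParams(D=LEEK_MOTH.D)


@pytest.fixture
def medfly_disp():
    return DispersalParams(D=MEDFLY.D)
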