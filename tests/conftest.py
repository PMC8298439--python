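import numpy as np
import pytest

from pkusim import BloodParams, PALKinetics, HUMAN_GUT, NHP_GUT


@pytest.fixture(scope="session")
def kin():
    """Default whole-cell PAL kinetics (calibration point estimates)."""
    return PALKinetics()


@pytest.fixture(scope="session")
def human_gut():
    return HUMAN_GUT


@pytest.fixture(scope="session")
def nhp_gut():
    return NHP_GUT


@pytest.fixture(scope="session")
def blood_params():
    return BloodParams()


def euler_batch(phe0, cells, ph, duration, kin, dt=0.001):
    """Independent fixed-step Euler oracle for the closed batch simulation."""
    from pkusim import pal_flux

    n = int(round(duration / dt))
    phe, tca = phe0, 0.0
    for _ in range(n):
        v = pal_flux(phe, cells, ph, tca, kin)
        phe -= v * dt
        tca += v * dt
        phe = max(phe, 0.0)
    return phe, tca
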