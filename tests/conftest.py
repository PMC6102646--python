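import warnings

import numpy as np
import pytest

from lvmech.geometry import LVGeometry
from lvmech.materials import load_material
from lvmech.mechanics import REDUCED_OPTIONS

warnings.filterwarnings("ignore", category=RuntimeWarning, module="lvmech")


@pytest.fixture(scope="session")
def failing_lv() -> LVGeometry:
    """Dilated failing-ventricle shape (end-diastolic HF-I-02 values)."""
    return LVGeometry(R_b=44.0, Z=52.0, L=9.5, H=5.7, e=0.65,
                      psi0=np.deg2rad(-75.0))


@pytest.fixture(scope="session")
def midsize_lv() -> LVGeometry:
    """Mid-size shape used across solver tests."""
    return LVGeometry(R_b=40.0, Z=53.0, L=10.0, H=5.9, e=0.65,
                      psi0=np.deg2rad(-75.0))


@pytest.fixture(scope="session")
def ellipsoid_lv() -> LVGeometry:
    """Ellipsoid-of-revolution limit (e=1, psi0 -> -pi/2)."""
    return LVGeometry(R_b=40.0, Z=53.0, L=10.0, H=5.0, e=1.0,
                      psi0=-np.pi / 2 + 1e-12)


@pytest.fixture(scope="session")
def usyk():
    return load_material("usyk")


@pytest.fixture(scope="session")
def whog():
    return load_material("whog")


@pytest.fixture(scope="session")
def whow():
    return load_material("whow")


@pytest.fixture(scope="session")
def opts():
    """Reduced study discretization (used everywhere speed matters)."""
    return REDUCED_OPTIONS


@pytest.fixture(scope="session")
def inflated_states(midsize_lv, usyk, whog, whow, opts):
    """2 kPa inflations of one shape under all three material sets."""
    from lvmech.mechanics import inflate

    return {
        m.name: inflate(midsize_lv, m, 2.0, opts) for m in (usyk, whog, whow)
    }
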