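import numpy as np
import pytest

from dendroiso import generate_world, synth_calibration_curve
from dendroiso.types import AnnualRecord, CalibrationCurve


@pytest.fixture(scope="session")
def world():
    """One default four-tree synthetic study shared across tests."""
    return generate_world(seed=42)


@pytest.fixture(scope="session")
def wiggly_curve():
    return synth_calibration_curve(span=(1300, 2015), bomb=True, seed=5)


@pytest.fixture()
def identity_curve():
    """μ(θ) = θ with zero curve error: Gaussian posteriors by construction."""
    bp = np.arange(-100.0, 1001.0)
    return CalibrationCurve(cal_bp=bp, c14_value=bp.copy(),
                            curve_sigma=np.zeros_like(bp), era="pre_bomb")


@pytest.fixture()
def flat_atm():
    years = np.arange(1300, 2016)
    return AnnualRecord(years=years, values=np.full(years.size, -6.3),
                        kind="d13c_atm")


@pytest.fixture()
def flat_co2():
    years = np.arange(1300, 2016)
    return AnnualRecord(years=years, values=np.full(years.size, 280.0),
                        kind="co2")
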