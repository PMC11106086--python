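import numpy as np
import pytest

from ringanchor.refcurve import CalibrationCurve, ReferenceCurve
from ringanchor.simulate import SimulationConfig


@pytest.fixture
def toy_reference():
    """Annual Delta-14C curve over 50 years with a visible event step."""
    years = np.arange(-5280, -5230)
    c = np.where(years >= -5258, 105.0, 90.0) + 0.1 * (years - years[0])
    return ReferenceCurve(int(years[0]), c, np.full(len(years), 1.5))


@pytest.fixture
def linear_calibration():
    """Strictly linear age-vs-calBP curve (slope 1), decadal knots."""
    calbp = np.arange(7000.0, 7301.0, 10.0)
    return CalibrationCurve(calbp, calbp - 800.0, np.full(len(calbp), 10.0))


@pytest.fixture
def config():
    return SimulationConfig(seed=1234)
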