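import numpy as np
import pytest

from pdqsp.model import calibrate_binding_anchor
from pdqsp.params import default_parameters

#: tumor burden (cells) at which the binding anchor is calibrated;
#: matches the day-7 burden of a 2e6-cell inoculum growing at the
#: population proliferation rate
CALIBRATION_BURDEN = 8.0e6


@pytest.fixture(scope="session")
def params():
    """Default parameters with the binding anchor calibrated."""
    return calibrate_binding_anchor(default_parameters(), CALIBRATION_BURDEN)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
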