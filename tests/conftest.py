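import numpy as np
import pytest

from cardiomaze.activity_metrics import measure_apd90
from cardiomaze.ionic_model import IschemiaParams, run_single_cell


@pytest.fixture(scope="session")
def healthy_trace():
    """Single healthy cell paced at 1 Hz for 5 beats (t, V)."""
    return run_single_cell(IschemiaParams(), sample_every=0.2)


@pytest.fixture(scope="session")
def hypoxic_trace():
    """[ATP]i = 3 mM, everything else healthy."""
    return run_single_cell(IschemiaParams(atp_i=3.0), sample_every=0.2)


@pytest.fixture(scope="session")
def combo_trace():
    """Combined ischemia: [ATP]i = 4 mM, [K]o = 7 mmol/l, 50% gCaL/gNa."""
    return run_single_cell(
        IschemiaParams(atp_i=4.0, k_o=7.0, f_gcal=0.5, f_gna=0.5),
        sample_every=0.2)


def apd_of(trace):
    apd = measure_apd90(*trace)
    assert apd is not None
    return apd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
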