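import numpy as np
import pytest

import mimacro as mm


@pytest.fixture(scope="session")
def default_p():
    return mm.default_params()


@pytest.fixture(scope="session")
def calibration_result():
    """E2 calibration of the default set (expensive; shared across tests)."""
    return mm.calibrate_to_equilibrium(mm.default_params())


@pytest.fixture(scope="session")
def mi_scenario(calibration_result):
    cal = calibration_result
    u = mm.mi_profile(base_rate=cal.diagnostics["baseline_monocyte_rate"])
    s0 = mm.ModelState(2000.0, 0.0, 0.0, 0.1, 0.1, 0.1)
    return cal.fitted_params, u, s0


@pytest.fixture(scope="session")
def mi_trajectory(mi_scenario):
    p, u, s0 = mi_scenario
    return mm.integrate(s0, p, u, (0.0, 30.0))


@pytest.fixture
def zero_inputs():
    return mm.constant_profile(0.0, 0.0, t_max=1e9)
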