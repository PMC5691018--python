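import numpy as np
import pytest

import pioncorr as pc


@pytest.fixture(scope="session")
def cal_10fff():
    return pc.load_builtin_calibration("10FFF")


@pytest.fixture(scope="session")
def cal_6fff():
    return pc.load_builtin_calibration("6FFF")


@pytest.fixture(scope="session")
def cal_flat():
    return pc.load_builtin_calibration("6/10MV")


def make_zero_slope_cal(energy_label="10FFF", intercept=1.0):
    """Calibration with no signal dependence: every correction reduces to
    the identity (in ratio quantities)."""
    return pc.PionCalibration(
        energy_label=energy_label,
        slope_m=0.0,
        intercept_b=intercept,
        slope_interval=(0.0, 0.0),
        intercept_interval=(intercept, intercept),
        r_squared=1.0,
        fitted_support=(0.0, 120.0),
    )


@pytest.fixture
def zero_cal():
    return make_zero_slope_cal


@pytest.fixture(scope="session")
def depth_grid():
    return np.round(np.arange(0.2, 35.0 + 1e-9, 0.2), 10)


@pytest.fixture(scope="session")
def crossplane_grid():
    return np.round(np.arange(-5.0, 5.0 + 1e-9, 0.05), 10)
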