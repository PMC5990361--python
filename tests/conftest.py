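import numpy as np
import pytest

import fretquant as fq


@pytest.fixture(scope="session")
def nadp_ratio_37C():
    """37 C emission-ratio calibration of the NADPH/NADP+ sensor."""
    return fq.get_calibration("nadp-37C-ratio")


@pytest.fixture(scope="session")
def nad_ratio_37C():
    return fq.get_calibration("nad-37C-ratio")


@pytest.fixture(scope="session")
def nadp_flim_37C():
    return fq.get_calibration("nadp-37C-flim")


@pytest.fixture(scope="session")
def nad_flim_37C():
    return fq.get_calibration("nad-37C-flim")


@pytest.fixture
def simple_nadp():
    """Hand-checkable NADP+-concentration calibration set."""
    return fq.CalibrationParams(sensor_kind="NADP", R_max=4.0, R_min=1.0,
                                c50=10.0, c50_unit="uM")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
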