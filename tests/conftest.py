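import numpy as np
import pytest

from astig3d import (CameraModel, FocusLevelSummary, default_calibration,
                     fit_ratio_polynomial)

#: coefficients of the bench ratio-to-depth relation used throughout
BENCH_COEFFS = (2.4, 2.8, 1.2)
CAL_LEVELS_UM = (-0.5, -0.25, 0.0, 0.25, 0.5)


def bench_ratio(z):
    a, b, c = BENCH_COEFFS
    return a * z**2 + b * z + c


@pytest.fixture(scope="session")
def bench_curve():
    """Ratio calibration rebuilt from noiseless samples of the bench
    relation at the five calibration depths."""
    levels = [
        FocusLevelSummary(z_um=z, mean_sigma_x=200.0 * bench_ratio(z),
                          mean_sigma_y=200.0, n_spots=10)
        for z in CAL_LEVELS_UM
    ]
    return fit_ratio_polynomial(levels, z_range=(-0.5, 0.5))


@pytest.fixture(scope="session")
def sim_curve():
    """Default ground-truth calibration used by the analytic renderer."""
    return default_calibration()


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
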