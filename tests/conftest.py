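import numpy as np
import pytest

from abkinetics import KineticParams, make_target_series, simulate


@pytest.fixture(scope="session")
def fitted_params() -> KineticParams:
    """The packaged fitted Tg2576 parameter set."""
    return KineticParams()


@pytest.fixture(scope="session")
def study_target():
    """The logistic soluble-Aβ42 target sampled at months 1..27."""
    return make_target_series()


@pytest.fixture(scope="session")
def fitted_trajectory(fitted_params):
    """Forward integration of the fitted model on the monthly grid."""
    return simulate(fitted_params)


@pytest.fixture(scope="session")
def monthly_grid():
    return np.arange(1, 28, dtype=float)
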