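import numpy as np
import pytest

from leatherback import (
    ConversionParams,
    default_growth_params,
    pacific_nesting_params,
    pacific_schedule,
)


@pytest.fixture(scope="session")
def gp():
    """Central growth parameters, t0 anchored to the 0.046 kg hatchling."""
    return default_growth_params()


@pytest.fixture(scope="session")
def cp():
    return ConversionParams()


@pytest.fixture(scope="session")
def nesting():
    return pacific_nesting_params()


@pytest.fixture(scope="session")
def mean_schedule():
    return pacific_schedule("mean")


@pytest.fixture(scope="session")
def age_grid():
    return np.arange(0.0, 40.0 + 1e-9, 1.0 / 52.0)
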