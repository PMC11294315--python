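import numpy as np
import pytest

from sltbeta import IndifferencePointSeries, generate_synthetic_cohort

#: delay grid whose hyperbolic means stay in roughly [0.1, 0.9] for
#: k = exp(-4.9); keeps beta shapes above 1 so interior-data behaviour
#: is well separated from endpoint behaviour
MODERATE_DELAYS = np.array([15.0, 40.0, 100.0, 250.0, 500.0, 800.0, 1200.0])


@pytest.fixture
def delays():
    return MODERATE_DELAYS.copy()


@pytest.fixture
def noiseless_series(delays):
    k = 0.05
    return IndifferencePointSeries("clean", delays, 1.0 / (1.0 + k * delays))


@pytest.fixture
def boundary_series(delays):
    return IndifferencePointSeries(
        "edge", delays, np.array([1.0, 0.9, 0.7, 0.5, 0.3, 0.1, 0.0])
    )


@pytest.fixture
def small_cohort():
    return generate_synthetic_cohort(8, seed=123)
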