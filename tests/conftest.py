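import numpy as np
import pytest

from acsidm import THETA_TRUE, SolveSpec, load_reference_table

MONITORING_TIMES = np.arange(0.0, 101.0, 10.0)

#: Admissible parameter box used by randomized property tests: onset in
#: adulthood, incidence slope of order 1e-4..1e-3, Gompertz mortalities
#: in a demographically plausible range (hazard at age 100 stays below
#: ~exp(2) per year, which also keeps the 0.1-year RK4 grid stable).
ADMISSIBLE_LOW = np.array([20.0, 1e-4, -12.0, 0.05, -12.0, 0.05])
ADMISSIBLE_HIGH = np.array([40.0, 1e-3, -9.0, 0.11, -9.0, 0.11])


@pytest.fixture(scope="session")
def theta_true():
    return THETA_TRUE


@pytest.fixture(scope="session")
def monitoring_times():
    return MONITORING_TIMES


@pytest.fixture(scope="session")
def default_spec():
    return SolveSpec(t_start=0.0, t_end=100.0, step=0.1)


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()
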