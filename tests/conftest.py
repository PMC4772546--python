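import numpy as np
import pytest

from dirfsim import CohortConfig, DosingSchedule, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture()
def fast_cfg():
    """Tiny cohort configuration for smoke-level simulations."""
    return CohortConfig(n_patients=4, dt=0.1, horizon=30.0, base_seed=7)


@pytest.fixture()
def braf_schedule():
    return DosingSchedule("BRAF_I", dose=1.0, days_on=21, days_off=7, horizon=360)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
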