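import numpy as np
import pytest

from oddpupil import synthetic_data as sd
from oddpupil import task_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def schedule():
    return task_design.build_schedule("S001", seed=1)


@pytest.fixture(scope="session")
def clean_params():
    return sd.clean_params()


@pytest.fixture(scope="session")
def small_cohort(clean_params):
    """Six subjects, blocks 1 and 3 (one per manipulation half), clean data."""
    return sd.simulate_cohort(clean_params, (2, 2, 2), seed=11, blocks=(1, 3))
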