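import numpy as np
import pytest

from somnocal import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=0)


@pytest.fixture(scope="session")
def cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def male_runner(cohort):
    return next(s for s in cohort if s.group == "male_runner")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
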