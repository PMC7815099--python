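import numpy as np
import pytest
from hypothesis import settings

from vectsick import pipeline, synthetic

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort_config():
    """A 19-participant cohort with short trials so trace-level tests stay fast."""
    return synthetic.SyntheticCohortConfig(seed=202, duration_s=90.0)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return synthetic.generate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    return pipeline.features_from_records(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
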