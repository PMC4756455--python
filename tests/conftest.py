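import numpy as np
import pytest

from twinmeta.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default 36-sample twin cohort used by read-only tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
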