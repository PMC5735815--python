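import numpy as np
import pytest

from proxymi import CohortParams, generate_cohort


@pytest.fixture(scope="session")
def default_params() -> CohortParams:
    return CohortParams()


@pytest.fixture(scope="session")
def big_cohort(default_params):
    """One large cohort shared by the moment-convergence checks."""
    return generate_cohort(default_params.with_n(1_000_000), np.random.SeedSequence(20171219))
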