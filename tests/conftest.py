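import numpy as np
import pytest

from opdemand import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study, shared across read-only tests."""
    return simulate_cohort(CohortSpec(seed=20240117))


@pytest.fixture(scope="session")
def small_spec():
    """A reduced cohort for tests that refit or rerun the pipeline."""
    return CohortSpec(n_subjects=8, seed=99, n_missing={})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
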