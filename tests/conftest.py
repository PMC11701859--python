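import numpy as np
import pytest

from neurofuse import default_cohort_spec, generate_cohort
from neurofuse.training import TrainConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for plumbing tests (not for recovery claims)."""
    return generate_cohort(default_cohort_spec(n_subjects=48, seed=7))


@pytest.fixture(scope="session")
def quick_config():
    """Deliberately tiny training schedule for wiring tests."""
    return TrainConfig(mode="two_stage", stage1_epochs=2, max_epochs=4,
                       gru_hidden=8, seed=0)
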