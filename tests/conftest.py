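import numpy as np
import pytest

from srckit import GammaPrior, worked_case_fixture
from srckit.bowtie import counts_per_interval


@pytest.fixture(scope="session")
def worked_case():
    """MDF-plant first-level scenario, ten-interval log, seqobs strings."""
    return worked_case_fixture()


@pytest.fixture(scope="session")
def worked_counts(worked_case):
    scenario, series, _ = worked_case
    return counts_per_interval(scenario, series.records, series.horizon)


@pytest.fixture(scope="session")
def zero_target_prior():
    """Near-zero-accident target: gamma(0.001, 0.001)."""
    return GammaPrior(alpha=0.001, beta=0.001)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
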