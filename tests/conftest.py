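import numpy as np
import pytest

from epiamp import CohortConfig, NoiseModel, make_amplicon, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Small amplicon (5 CpGs, 120 bp) reused across read-level tests."""
    return make_amplicon(5, 120, seed=11, name="mini")


@pytest.fixture(scope="session")
def tph1a_like():
    return make_amplicon(11, 318, seed=42, name="Tph1A_like")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Desk-scale cohort shared by pipeline-level tests."""
    cfg = CohortConfig(reads_per_sample=250, control_reads=200)
    return simulate_cohort(cfg, seed=202)


@pytest.fixture
def no_noise():
    return NoiseModel(incomplete_conversion=0.0, over_conversion=0.0,
                      seq_error=0.0, hmc_fraction=0.0)
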