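import numpy as np
import pytest

from dnmp.config import DecoderConfig, StudyConfig
from dnmp.simulate import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Three sessions x six units with the default planted modulations."""
    cfg = StudyConfig(n_sessions=3, n_animals=1, neurons_per_session=6)
    return generate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def flat_cohort():
    """Five sessions x eight units, no modulation anywhere (null data)."""
    cfg = StudyConfig(n_sessions=5, n_animals=1, neurons_per_session=8,
                      modulations=())
    return generate_cohort(cfg, seed=202)


@pytest.fixture(scope="session")
def flat_tensors(flat_cohort):
    from dnmp.binning import compute_rate_tensor
    return [compute_rate_tensor(s) for s in flat_cohort.sessions]


@pytest.fixture(scope="session")
def small_tensors(small_cohort):
    from dnmp.binning import compute_rate_tensor
    return [compute_rate_tensor(s) for s in small_cohort.sessions]


@pytest.fixture
def quick_decoder_config():
    return DecoderConfig(n_iterations=20, n_shuffles=20)


@pytest.fixture(scope="session")
def medium_cohort():
    """Ten sessions x ten units with the default planted modulations."""
    cfg = StudyConfig(n_sessions=10, n_animals=5, neurons_per_session=10)
    return generate_cohort(cfg, seed=303)


@pytest.fixture(scope="session")
def medium_tensors(medium_cohort):
    from dnmp.binning import compute_rate_tensor
    return [compute_rate_tensor(s) for s in medium_cohort.sessions]
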