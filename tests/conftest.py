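import numpy as np
import pytest

from ddehm import make_case_study


@pytest.fixture(scope="session")
def tfa_datasets():
    """Standard noisy TF-A case-study splits (shared across tests)."""
    return make_case_study("tfa", master_seed=1)


@pytest.fixture(scope="session")
def pichia_datasets():
    return make_case_study("pichia", master_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
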