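import numpy as np
import pytest

from lizonc import datasets


@pytest.fixture(scope="session")
def lit_cohort():
    return datasets.synthetic_literature_cohort()


@pytest.fixture(scope="session")
def escra_cohort():
    return datasets.synthetic_escra_cohort()


@pytest.fixture(scope="session")
def combined_cohort():
    return datasets.synthetic_combined_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(20240507)
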