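import numpy as np
import pytest

from krtdose import load_drug_library, sample_cohort


@pytest.fixture(scope="session")
def library():
    return load_drug_library()


@pytest.fixture(scope="session")
def cefepime(library):
    return library["cefepime"]


@pytest.fixture(scope="session")
def small_cefepime_cohort(cefepime):
    """A modest cohort for fast end-to-end checks."""
    return sample_cohort(cefepime, 400, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
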