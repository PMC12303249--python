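import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("default", deadline=None)
hypothesis_settings.load_profile("default")

from gtaccess import (
    CohortConfig,
    default_lexicon,
    extract_corpus,
    generate_cohort,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def cohort200():
    return generate_cohort(CohortConfig(n_patients=200, seed=11))


@pytest.fixture(scope="session")
def cohort200_docs(cohort200, lexicon):
    _, docs = extract_corpus(cohort200.notes, lexicon)
    return docs


@pytest.fixture(scope="session")
def big_cohort():
    """2000-patient calibration cohort (shared: generation is ~10 s)."""
    return generate_cohort(CohortConfig(n_patients=2000, seed=7))


@pytest.fixture(scope="session")
def big_cohort_extraction(big_cohort, lexicon):
    snippets, docs = extract_corpus(big_cohort.notes, lexicon)
    return snippets, docs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
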