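import numpy as np
import pytest

from resilmine.corpus import preprocess_corpus
from resilmine.synth import default_spec, generate_corpus


@pytest.fixture(scope="session")
def study_corpus():
    """The seeded synthetic study corpus plus its ground truth."""
    return generate_corpus(default_spec(seed=11))


@pytest.fixture(scope="session")
def study_seqs(study_corpus):
    corpus, _ = study_corpus
    return preprocess_corpus(corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
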