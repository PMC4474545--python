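import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clinsbd.stats import count_collocations
from clinsbd.synth import GeneratorConfig, generate_corpus, generate_lexicons
from clinsbd.text import tokenize

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicons():
    return generate_lexicons(seed=7)


@pytest.fixture(scope="session")
def small_corpus(lexicons):
    mddict, ccdict = lexicons
    cfg = GeneratorConfig(n_sentences=120, seed=7)
    text, gold = generate_corpus(cfg, mddict, ccdict)
    return text, gold


@pytest.fixture(scope="session")
def small_table(small_corpus):
    text, _ = small_corpus
    return count_collocations(tokenize(text))


@pytest.fixture(scope="session")
def abbrev_labels(small_corpus):
    _, gold = small_corpus
    return np.array([int(s.is_abbrev) for s in gold])


@pytest.fixture(scope="session")
def sentence_labels(small_corpus):
    _, gold = small_corpus
    return np.array([int(s.is_sentence_end) for s in gold])
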