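import numpy as np
import pytest

from qoltopics import (GeneratorConfig, GibbsLDA, LexiconSet, generate_corpus,
                       stub_lexicons)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small well-separated corpus with ground truth, shared across tests."""
    cfg = GeneratorConfig(K=3, V=60, D=80, seed=11, mean_length=25,
                          beta_gen=0.01)
    corpus, truth = generate_corpus(cfg)
    return cfg, corpus, truth


@pytest.fixture(scope="session")
def small_model(small_synthetic):
    _, corpus, _ = small_synthetic
    return GibbsLDA(n_topics=3, n_iter=300, burn_in=100,
                    random_state=5).fit(corpus)


@pytest.fixture
def french_lexicons():
    return LexiconSet(
        medical_terms={"cancer", "chimiothérapie", "cancer du sein",
                       "tamoxifène", "douleur"},
        lay_to_medical={"crabe": "cancer", "chimio": "chimiothérapie"},
        stopwords={"le", "la", "de", "et", "un"},
        slang={"lol", "mdr", "xD"},
        pseudonyms={"rose75"},
        noise_terms=set(),
        spelling_dictionary={"cancerr": "cancer"},
    )
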