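import pytest

from persent import NormalizeConfig, default_rules, demo_lexicon
from persent.pipeline import normalize_corpus, score_corpus
from persent.synthetic import GeneratorConfig, generate_corpus, generate_lexicon, noise_free


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def demo_lex():
    return demo_lexicon()


@pytest.fixture(scope="session")
def gen_lex():
    return generate_lexicon(40, seed=1)


@pytest.fixture(scope="session")
def small_corpus(rules, gen_lex):
    """A noise-free 120-document corpus with ground truth."""
    cfg = noise_free(GeneratorConfig(n_docs=120, seed=17))
    comments, truth = generate_corpus(cfg, gen_lex, rules)
    return comments, truth


@pytest.fixture(scope="session")
def scored_small_corpus(small_corpus, rules, gen_lex):
    comments, truth = small_corpus
    docs = normalize_corpus(comments, rules, gen_lex, NormalizeConfig())
    scores = score_corpus(docs, gen_lex)
    return docs, scores, truth
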