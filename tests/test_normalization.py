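import numpy as np
import pytest

from persent import RawComment, normalize_pipeline
from persent.errors import EmptyDocumentError
from persent.normalization import (
    ZWNJ,
    normalize_affixes,
    normalize_characters,
    normalize_spacing,
    normalize_spelling,
    remove_punctuation,
    remove_stopwords,
    spell_check,
    split_sentences,
    stem,
    tokenize,
)
from persent.synthetic import GeneratorConfig, NoiseRates, corrupt_surface


@pytest.mark.parametrize(
    "text,expected",
    [
        ("كيف", "کیف"),  # Arabic kaf/yeh -> Persian forms
        ("اب", "آب"),  # madda restoration from the word list
        ("سلام", "سلام"),  # already canonical
    ],
)
def test_character_unification(rules, text, expected):
    assert normalize_characters(text, rules) == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("بــــــر", "بر"),  # kashida elongation removed
        ("سلام   دنیا", "سلام دنیا"),
        ("", ""),
        (" سلام\tدنیا ", "سلام دنیا"),
    ],
)
def test_spacing(rules, text, expected):
    assert normalize_spacing(text, rules) == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("مناسب تر", "مناسبتر"),  # detached suffix reattached
        ("می رود", "می" + ZWNJ + "رود"),  # prefix joined with half-space
        ("خوب", "خوب"),
        ("خوب. تر", "خوب. تر"),  # never merge across a sentence boundary
    ],
)
def test_affix_reattachment(rules, text, expected):
    assert normalize_affixes(text, rules) == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("اطاق", "اتاق"),
        ("پیر مرد", "پیرمرد"),  # compound unified
        ("ناشناخته", "ناشناخته"),  # absent from the map
    ],
)
def test_spelling_unification(rules, text, expected):
    assert normalize_spelling(text, rules) == expected


@pytest.mark.parametrize(
    "text,expected",
    [("خوب!", "خوب"), ("(تست)", "تست"), ("بدون علامت", "بدون علامت")],
)
def test_punctuation_removal(rules, text, expected):
    assert remove_punctuation(text, rules) == expected


@pytest.mark.parametrize(
    "text,n", [("الف. ب!", 2), ("بدون نقطه", 1), ("", 0), ("یک؟ دو؛ سه\nچهار", 4)]
)
def test_sentence_splitting(text, n):
    assert len(split_sentences(text)) == n


def test_tokenize_keeps_half_space():
    assert tokenize("می" + ZWNJ + "رود خوب") == ["می" + ZWNJ + "رود", "خوب"]
    assert tokenize("") == []


def test_stopword_removal(rules):
    assert remove_stopwords(["از", "خوب"], rules) == ["خوب"]
    assert remove_stopwords([], rules) == []
    assert remove_stopwords(["از", "به"], rules) == []


@pytest.mark.parametrize(
    "token,expected",
    [
        ("مناسبتر", "مناسب"),
        ("خوب", "خوب"),
        ("تر", "تر"),  # stripping would empty the token
        ("کتاب" + ZWNJ + "ها", "کتاب"),
        ("مناسبترین", "مناسب"),
    ],
)
def test_stemming(rules, token, expected):
    assert stem(token, rules.suffixes) == expected


def test_spell_check_conservative():
    vocab = {"بیمار", "پرستار"}
    # unique distance-1 correction
    assert spell_check(["بیمارر"], vocab) == ["بیمار"]
    # in-vocabulary tokens never altered
    assert spell_check(["پرستار"], vocab) == ["پرستار"]
    # ambiguous (two candidates at distance 1) -> unchanged
    assert spell_check(["خوبب"], {"خوب", "خواب"}) == ["خوبب"]
    # distance > 1 -> unchanged
    assert spell_check(["قفسه"], vocab) == ["قفسه"]


def test_pipeline_composes_stages(rules, demo_lex):
    doc = normalize_pipeline(
        RawComment("x", "general_services", "اطاق خوب!"), rules, demo_lex
    )
    assert len(doc.sentences) == 1
    assert doc.surfaces() == ["اتاق", "خوب"]


def test_pipeline_empty_document_raises(rules, demo_lex):
    with pytest.raises(EmptyDocumentError):
        normalize_pipeline(RawComment("x", "general_services", "!!!"), rules, demo_lex)


def test_pipeline_idempotent_on_own_output(rules, demo_lex):
    text = "می رود مناسب تر. اطاق بــــر خوب است!"
    doc = normalize_pipeline(RawComment("x", "general_services", text), rules, demo_lex)
    rebuilt = " ".join(" ".join(t.surface for t in s.tokens) + "." for s in doc.sentences)
    doc2 = normalize_pipeline(
        RawComment("x", "general_services", rebuilt), rules, demo_lex
    )
    assert doc2.surfaces() == doc.surfaces()
    assert [t.stem for s in doc2.sentences for t in s.tokens] == [
        t.stem for s in doc.sentences for t in s.tokens
    ]


def _random_noisy_texts(rules, n):
    cfg = GeneratorConfig(
        surface_noise_rates=NoiseRates(0.4, 0.4, 0.4, 0.4, 0.4, 0.4, 0.4)
    )
    rng = np.random.default_rng(99)
    base_words = ["آزمایش", "اتاق", "مناسبتر", "می‌رود", "خوب", "شیمی‌درمانی", "دکتر"]
    for i in range(n):
        k = rng.integers(1, 8)
        words = [base_words[j] for j in rng.integers(0, len(base_words), k)]
        clean = " ".join(words) + "."
        yield corrupt_surface(clean, cfg, int(rng.integers(2**31)), rules)


@pytest.mark.parametrize(
    "op",
    [
        normalize_characters,
        normalize_spacing,
        normalize_affixes,
        normalize_spelling,
        remove_punctuation,
    ],
)
def test_text_operations_idempotent(rules, op):
    """O(O(x)) == O(x) for each text-level operation on noisy inputs."""
    for text in _random_noisy_texts(rules, 60):
        once = op(text, rules)
        assert op(once, rules) == once


def test_token_count_preserved_by_non_affix_normalization(rules):
    """Character, spacing and spelling normalization never change the number
    of single-word tokens (merges come only from affix/compound rules)."""
    texts = ["كيف خوب اب", "بــــر  سلام\tدنیا", "اطاق تمیز بود"]
    for text in texts:
        n0 = len(tokenize(normalize_spacing(text, rules)))
        t = normalize_characters(text, rules)
        t = normalize_spacing(t, rules)
        assert len(tokenize(t)) == n0
        # single-word spelling variants replace in place
        t2 = normalize_spelling(t, rules)
        assert len(tokenize(t2)) == len(tokenize(t))
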