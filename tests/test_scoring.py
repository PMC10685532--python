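import numpy as np
import pytest

from persent import SentimentLexicon, aggregate_scores, classify, score_document, score_sentence
from persent.errors import LengthMismatchError, WeightError
from persent.lexicon import lookup
from persent.normalization import NormalizedDocument, Sentence, Token
from persent.scoring import term_frequency_report, topic_sentiment


def _tok(stem, negated=False):
    return Token(stem, stem, negated)


def _doc(*sentence_stems, comment_id="d"):
    sentences = tuple(
        Sentence(i, tuple(_tok(s) for s in stems))
        for i, stems in enumerate(sentence_stems)
    )
    return NormalizedDocument(comment_id, sentences, "general_services")


LEX = SentimentLexicon({"pos3": 3, "pos1": 1, "neg2": -2, "neg3": -3, "neg5": -5})


def _brute_force(tokens, lexicon):
    """Independent oracle: enumerate every lookup, take max/min, max-abs rule."""
    strengths = [s for s in (lookup(lexicon, t) for t in tokens) if s is not None]
    max_pos = max([s for s in strengths if s > 0], default=0)
    min_neg = min([s for s in strengths if s < 0], default=0)
    if max_pos == -min_neg:
        polarity = 0
    else:
        polarity = max_pos if max_pos > -min_neg else min_neg
    return max_pos, min_neg, polarity


def test_sentence_examples():
    s = score_sentence([_tok("pos3"), _tok("neg2")], LEX)
    assert (s.max_pos, s.min_neg, s.polarity) == (3, -2, 3)
    s = score_sentence([_tok("unknown")], LEX)
    assert (s.max_pos, s.min_neg, s.polarity) == (0, 0, 0)
    s = score_sentence([_tok("pos3"), _tok("neg3")], LEX)
    assert s.polarity == 0  # exact tie is neutral


def test_sentence_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    entries = {f"t{i}": int(s) for i, s in enumerate(rng.choice([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5], 30))}
    lex = SentimentLexicon(entries)
    terms = list(entries) + ["zz1", "zz2"]
    for _ in range(1000):
        n = rng.integers(0, 12)
        tokens = [
            _tok(terms[rng.integers(len(terms))], bool(rng.integers(2)))
            for _ in range(n)
        ]
        got = score_sentence(tokens, lex)
        assert (got.max_pos, got.min_neg, got.polarity) == _brute_force(tokens, lex)


def test_negation_flips_single_term_polarity():
    for stem, s in LEX.entries.items():
        plain = score_sentence([_tok(stem)], LEX).polarity
        negated = score_sentence([Token(stem, stem, True)], LEX).polarity
        assert negated == -plain


def test_positive_strength_monotonicity():
    """Raising one positive term's strength never decreases sentence polarity."""
    base = [_tok("neg2"), _tok("x")]
    prev = None
    for s in range(1, 6):
        lex = SentimentLexicon({"x": s, "neg2": -2})
        pol = score_sentence(base, lex).polarity
        if prev is not None:
            assert pol >= prev
        prev = pol


def test_document_score_examples():
    d = score_document(_doc(["pos3"], ["neg2"]), LEX)
    assert d.score == pytest.approx((3 - 2) / 2 / 5) and d.label == "positive"
    d = score_document(_doc(["x"], ["y"]), LEX)
    assert d.score == 0.0 and d.label == "neutral"
    d = score_document(_doc(["neg5"]), LEX)
    assert d.score == -1.0 and d.label == "negative"


def test_document_score_bounded():
    rng = np.random.default_rng(3)
    terms = list(LEX.entries) + ["u"]
    for _ in range(200):
        stems = [[terms[rng.integers(len(terms))] for _ in range(rng.integers(1, 5))]
                 for _ in range(rng.integers(1, 5))]
        d = score_document(_doc(*stems), LEX)
        assert -1.0 <= d.score <= 1.0


def test_aggregate_weighted_example():
    agg = aggregate_scores([0.5, -0.5, 0.1], [2, 1, 1])
    assert agg.V == pytest.approx(0.15)
    assert aggregate_scores([0.4, -0.2]).V == pytest.approx(0.1)
    assert aggregate_scores([0.37]).V == 0.37


def test_aggregate_equal_weights_is_arithmetic_mean():
    rng = np.random.default_rng(11)
    for _ in range(100):
        vals = rng.uniform(-1, 1, rng.integers(1, 40))
        agg = aggregate_scores(list(vals))
        assert abs(agg.V - float(np.mean(vals))) < 1e-12
        assert min(vals) <= agg.V <= max(vals)


def test_aggregate_errors():
    with pytest.raises(WeightError):
        aggregate_scores([0.1], [-1.0])
    with pytest.raises(WeightError):
        aggregate_scores([0.1, 0.2], [0.0, 0.0])
    with pytest.raises(LengthMismatchError):
        aggregate_scores([0.1], [1.0, 1.0])


@pytest.mark.parametrize(
    "score,band,label",
    [(0.1, 0.0, "positive"), (-0.004, 0.01, "neutral"), (0.0, 0.0, "neutral"),
     (-0.2, 0.0, "negative")],
)
def test_classify(score, band, label):
    assert classify(score, band) == label


def test_topic_sentiment_shares():
    docs = [
        score_document(_doc(["pos1"], comment_id="a"), LEX),
        score_document(_doc(["pos3", "pos1"], comment_id="b"), LEX),
        score_document(_doc(["neg3"], comment_id="c"), LEX),
    ]
    # a: 0.2, b: 0.6, c: -0.6
    aggs = topic_sentiment(docs, {"a": 0, "b": 0, "c": 1}, 3)
    assert aggs[0].V == pytest.approx(0.4) and aggs[0].share == pytest.approx(2 / 3)
    assert aggs[1].V == pytest.approx(-0.6) and aggs[1].n == 1
    assert aggs[2].n == 0 and aggs[2].V is None


def test_term_frequency_ranking():
    docs = [_doc(["خوب", "خوب", "بد"]), _doc(["خوب", "خوب", "خوب", "بد"])]
    assert term_frequency_report(docs, 5) == [("خوب", 5), ("بد", 2)]
    assert term_frequency_report([], 5) == []
    assert term_frequency_report(docs, 1) == [("خوب", 5)]
    # ties break lexicographically
    docs = [_doc(["ب", "آ"])]
    assert term_frequency_report(docs, 2) == [("آ", 1), ("ب", 1)]
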