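import itertools

import numpy as np
import pytest

from persent import auc, compute_metrics, confusion, rating_to_label, split_corpus
from persent.errors import (
    LengthMismatchError,
    NonBinaryLabelError,
    RatingRangeError,
    SingleClassError,
)
from persent.evaluation import ConfusionMatrix, evaluate_sections

P, N = "positive", "negative"


@pytest.mark.parametrize("rating,label", [(3, P), (4, P), (5, P), (1, N), (2, N)])
def test_rating_to_label(rating, label):
    assert rating_to_label(rating) == label


def test_rating_out_of_range():
    with pytest.raises(RatingRangeError):
        rating_to_label(6)


def test_split_sizes_and_reproducibility():
    ids = list(range(100))
    train, test = split_corpus(ids, 0.9, seed=4)
    assert len(train) == 90 and len(test) == 10
    assert sorted(train + test) == ids
    assert split_corpus(ids, 0.9, seed=4) == (train, test)
    assert split_corpus(ids, 0.9, seed=5) != (train, test)


def test_split_stratified_largest_remainder():
    ids = list(range(10))
    labels = [P] * 5 + [N] * 5
    train, test = split_corpus(ids, 0.9, seed=0, labels=labels)
    assert len(test) == 1 and len(train) == 9
    # a larger stratified split keeps class proportions within one item
    ids = list(range(200))
    labels = [P] * 140 + [N] * 60
    _, test = split_corpus(ids, 0.9, seed=1, labels=labels)
    n_pos = sum(1 for i in test if labels[i] == P)
    assert n_pos == 14 and len(test) == 20


def test_confusion_enumeration():
    cm = confusion([P, P, N, N], [P, N, N, P])
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)
    perfect = confusion([P, N], [P, N])
    assert perfect.fp == perfect.fn == 0
    inverted = confusion([P, N], [N, P])
    assert inverted.tp == inverted.tn == 0
    with pytest.raises(NonBinaryLabelError):
        confusion([P], ["neutral"])
    with pytest.raises(LengthMismatchError):
        confusion([P], [P, N])


def test_metrics_closed_form_examples():
    m = compute_metrics(ConfusionMatrix(tp=9, fp=1, fn=1, tn=9))
    assert m.precision == m.recall == m.specificity == m.accuracy == m.f_measure == 0.9
    m = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=3, tn=5))
    assert m.precision is None and m.recall == 0.0
    m = compute_metrics(ConfusionMatrix(tp=8, fp=2, fn=4, tn=6))
    assert m.precision == pytest.approx(0.8)
    assert m.recall == pytest.approx(2 / 3)
    assert m.f_measure == pytest.approx(2 * 0.8 * (2 / 3) / (0.8 + 2 / 3))


def test_metrics_match_hand_formulas_on_random_matrices():
    rng = np.random.default_rng(8)
    for _ in range(200):
        tp, fp, fn, tn = (int(x) for x in rng.integers(0, 30, 4))
        if tp + fp + fn + tn == 0:
            tn = 1
        m = compute_metrics(ConfusionMatrix(tp, fp, fn, tn))
        assert m.accuracy == (tp + tn) / (tp + fp + fn + tn)
        assert m.precision == (tp / (tp + fp) if tp + fp else None)
        assert m.recall == (tp / (tp + fn) if tp + fn else None)
        assert m.specificity == (tn / (tn + fp) if tn + fp else None)
        if m.precision and m.recall:
            assert m.f_measure == 2 * m.precision * m.recall / (m.precision + m.recall)


def _auc_pairs(scores, labels):
    """Exhaustive pair-counting oracle (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l == P]
    neg = [s for s, l in zip(scores, labels) if l == N]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def test_auc_limits():
    assert auc([0.9, 0.8, 0.2, 0.1], [P, P, N, N]) == 1.0
    assert auc([0.5, 0.5, 0.5, 0.5], [P, P, N, N]) == 0.5
    assert auc([0.9, 0.4, 0.6, 0.1], [P, N, P, N]) == 1.0


def test_auc_matches_pair_oracle_up_to_length_12():
    rng = np.random.default_rng(21)
    for n in range(2, 13):
        for _ in range(80):
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], n)  # forces ties
            labels = [P if b else N for b in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                labels[0] = P if labels[0] == N else N
            assert auc(list(scores), labels) == pytest.approx(
                _auc_pairs(scores, labels), abs=1e-12
            )


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=50)
    labels = [P if b else N for b in rng.integers(0, 2, 50)]
    labels[0], labels[1] = P, N
    base = auc(list(scores), labels)
    assert auc(list(np.exp(scores)), labels) == pytest.approx(base)
    assert auc(list(3 * scores - 7), labels) == pytest.approx(base)


def test_auc_label_shuffle_is_chance_level():
    rng = np.random.default_rng(33)
    scores = rng.normal(size=10_000)
    labels = [P] * 5000 + [N] * 5000
    rng.shuffle(labels)
    assert 0.45 <= auc(list(scores), labels) <= 0.55


def test_auc_single_class_raises():
    with pytest.raises(SingleClassError):
        auc([0.1, 0.2], [P, P])


def test_evaluate_sections_shape():
    per_section = {}
    for sec in ("healthcare_services", "general_services", "life_expectancy"):
        scores = [0.8, 0.6, -0.4, -0.2]
        y_true = [P, P, N, N]
        y_pred = [P, P, N, N]
        per_section[sec] = (scores, y_true, y_pred)
    reports = evaluate_sections(per_section)
    assert len(reports) == 3
    for rep in reports.values():
        d = rep.as_dict()
        assert set(d) == {"precision", "recall", "specificity", "accuracy",
                          "f_measure", "auc"}
        assert all(v == 1.0 for v in d.values())
    # an empty section is omitted
    per_section["general_services"] = ([], [], [])
    assert set(evaluate_sections(per_section)) == {
        "healthcare_services", "life_expectancy"
    }
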