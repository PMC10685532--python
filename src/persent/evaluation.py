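"""Binary-classification evaluation: ratings to labels, 90:10 splits,
confusion matrix, precision/recall/specificity/accuracy/F-measure, AUC.

Ground-truth labels come from 1-5 expert ratings: 3, 4 and 5 are positive,
1 and 2 negative. Any metric with a zero denominator is reported as an
explicit ``None`` marker rather than raising. AUC is the rank-based
(Mann-Whitney) statistic with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import (
    EmptyMatrixError,
    LengthMismatchError,
    NonBinaryLabelError,
    RatingRangeError,
    SingleClassError,
)
from .scoring import NEGATIVE, POSITIVE

BINARY_LABELS = (POSITIVE, NEGATIVE)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float | None
    recall: float | None
    specificity: float | None
    accuracy: float | None
    f_measure: float | None
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
            "auc": self.auc,
        }


def rating_to_label(rating: int) -> str:
    """Ratings 3-5 are positive, 1-2 negative."""
    if rating not in (1, 2, 3, 4, 5):
        raise RatingRangeError(f"rating {rating!r} not in 1..5")
    return POSITIVE if rating >= 3 else NEGATIVE


def split_corpus(
    ids: Sequence,
    ratio: float,
    seed: int,
    labels: Sequence | None = None,
) -> tuple[list, list]:
    """Reproducible train/test split; |test| = round((1-ratio)*n).

    With labels supplied the split is stratified: per-stratum test quotas
    are apportioned by largest remainder, so class proportions carry over
    as closely as integer counts allow.
    """
    n = len(ids)
    if n < 2:
        raise LengthMismatchError("need at least 2 items to split")
    if not 0 < ratio < 1:
        raise LengthMismatchError("ratio must lie strictly between 0 and 1")
    n_test = int(round((1 - ratio) * n))
    n_test = min(max(n_test, 0), n)
    rng = np.random.default_rng(seed)
    if labels is None:
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
    else:
        if len(labels) != n:
            raise LengthMismatchError("labels length must match ids")
        strata: dict[object, list[int]] = {}
        for i, lab in enumerate(labels):
            strata.setdefault(lab, []).append(i)
        exact = {lab: n_test * len(ix) / n for lab, ix in strata.items()}
        quota = {lab: int(np.floor(v)) for lab, v in exact.items()}
        short = n_test - sum(quota.values())
        for lab in sorted(
            strata, key=lambda l: (-(exact[l] - quota[l]), str(l))
        )[:short]:
            quota[lab] += 1
        test_idx = set()
        for lab, ix in sorted(strata.items(), key=lambda kv: str(kv[0])):
            picked = rng.permutation(len(ix))[: quota[lab]]
            test_idx.update(ix[i] for i in picked)
    train = [ids[i] for i in range(n) if i not in test_idx]
    test = [ids[i] for i in range(n) if i in test_idx]
    return train, test


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise LengthMismatchError("label vectors differ in length")
    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for t, p in zip(true_labels, predicted_labels):
        if t not in BINARY_LABELS or p not in BINARY_LABELS:
            raise NonBinaryLabelError(f"non-binary label pair ({t!r}, {p!r})")
        if t == POSITIVE:
            counts["tp" if p == POSITIVE else "fn"] += 1
        else:
            counts["fp" if p == POSITIVE else "tn"] += 1
    return ConfusionMatrix(**counts)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP),
    accuracy (TP+TN)/total, F = 2PR/(P+R); zero denominators yield None."""
    if cm.total == 0:
        raise EmptyMatrixError("confusion matrix is empty")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    accuracy = (cm.tp + cm.tn) / cm.total
    if precision is None or recall is None or precision + recall == 0:
        f_measure = None
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    return MetricsReport(precision, recall, specificity, accuracy, f_measure)


def auc(scores: Sequence[float], true_labels: Sequence[str]) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2."""
    if len(scores) != len(true_labels):
        raise LengthMismatchError("scores and labels differ in length")
    y = np.asarray([1 if t == POSITIVE else 0 for t in true_labels])
    if not ((y == 1).any() and (y == 0).any()):
        raise SingleClassError("AUC needs both classes present")
    ranks = rankdata(np.asarray(scores, dtype=float))
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate_sections(
    by_section: Mapping[str, tuple[Sequence[float], Sequence[str], Sequence[str]]],
) -> dict[str, MetricsReport]:
    """Per-section metric reports from (scores, true labels, predicted labels).

    Sections with no evaluable items are omitted. The returned mapping is
    the tabular shape used for reporting: one column per section, six
    metrics per column.
    """
    reports: dict[str, MetricsReport] = {}
    for section, (scores, y_true, y_pred) in by_section.items():
        if len(y_true) == 0:
            continue
        cm = confusion(y_true, y_pred)
        report = compute_metrics(cm)
        try:
            area = auc(scores, y_true)
        except SingleClassError:
            area = None
        reports[section] = MetricsReport(
            report.precision,
            report.recall,
            report.specificity,
            report.accuracy,
            report.f_measure,
            area,
        )
    return reports
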