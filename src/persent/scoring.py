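"""Sentence and document sentiment scoring and review-level aggregation.

Per sentence, the scorer takes the maximum positive and minimum negative
term strengths and keeps the one with the larger absolute value as the
sentence polarity (an exact tie is neutral). A document's score is the
mean of its nonzero sentence polarities divided by 5, which places it on
the reporting scale [-1 (most pessimistic), +1 (most optimistic)].
Review-level aggregation is the usefulness-weighted average

    V(P) = sum_i u(T_i(P)) * Polarity(T_i(P)) / sum_i u(T_i(P)),

which with equal weights reduces to the arithmetic mean of review scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import EmptyDocumentError, LengthMismatchError, WeightError
from .lexicon import SentimentLexicon, lookup
from .normalization import NormalizedDocument, Token

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class SentenceScore:
    max_pos: int  # in 0..5
    min_neg: int  # in -5..0
    polarity: int  # in -5..+5


@dataclass(frozen=True)
class DocumentScore:
    comment_id: str
    sentence_scores: tuple[SentenceScore, ...]
    score: float  # in [-1, +1]
    label: str
    section: str | None = None


@dataclass(frozen=True)
class AggregateScore:
    group_key: object
    V: float | None  # None when the group is empty
    n: int
    share: float | None = None  # fraction of all documents in this group


def score_sentence(tokens: Sequence[Token], lexicon: SentimentLexicon) -> SentenceScore:
    """Max-positive / min-negative strengths; larger magnitude wins, tie -> 0."""
    max_pos = 0
    min_neg = 0
    for tok in tokens:
        s = lookup(lexicon, tok)
        if s is None:
            continue
        if s > max_pos:
            max_pos = s
        if s < min_neg:
            min_neg = s
    if max_pos > -min_neg:
        polarity = max_pos
    elif -min_neg > max_pos:
        polarity = min_neg
    else:
        polarity = 0
    return SentenceScore(max_pos, min_neg, polarity)


def classify(score: float, neutral_band: float = 0.0) -> str:
    """Map a continuous score to positive/negative/neutral with a dead band."""
    if neutral_band < 0:
        raise WeightError("neutral_band must be >= 0")
    if score > neutral_band:
        return POSITIVE
    if score < -neutral_band:
        return NEGATIVE
    return NEUTRAL


def score_document(
    doc: NormalizedDocument,
    lexicon: SentimentLexicon,
    neutral_band: float = 0.0,
) -> DocumentScore:
    """Score every sentence, then average the nonzero polarities onto [-1, 1]."""
    if not doc.sentences:
        raise EmptyDocumentError(f"document {doc.comment_id} has no sentences")
    sent_scores = tuple(score_sentence(s.tokens, lexicon) for s in doc.sentences)
    nonzero = [s.polarity for s in sent_scores if s.polarity != 0]
    score = (sum(nonzero) / len(nonzero)) / 5.0 if nonzero else 0.0
    return DocumentScore(
        doc.comment_id, sent_scores, score, classify(score, neutral_band), doc.section
    )


def aggregate_scores(
    doc_scores: Sequence[DocumentScore | float],
    u_weights: Sequence[float] | None = None,
    group_key: object = None,
) -> AggregateScore:
    """Usefulness-weighted average of review scores (equal weights by default)."""
    values = [d.score if isinstance(d, DocumentScore) else float(d) for d in doc_scores]
    if u_weights is None:
        u_weights = [1.0] * len(values)
    if len(u_weights) != len(values):
        raise LengthMismatchError(
            f"{len(values)} scores but {len(u_weights)} weights"
        )
    if any(w < 0 for w in u_weights):
        raise WeightError("usefulness weights must be non-negative")
    total = float(sum(u_weights))
    if not values or total == 0.0:
        raise WeightError("sum of usefulness weights must be positive")
    v = sum(w * s for w, s in zip(u_weights, values)) / total
    return AggregateScore(group_key, v, len(values))


def topic_sentiment(
    doc_scores: Sequence[DocumentScore],
    dominant_topics: Mapping[str, int],
    k: int,
) -> list[AggregateScore]:
    """Equal-weight per-topic aggregate plus each topic's share of documents.

    Topics with no documents are reported with ``n=0`` and ``V=None``.
    """
    by_topic: dict[int, list[float]] = {t: [] for t in range(k)}
    for ds in doc_scores:
        topic = dominant_topics[ds.comment_id]
        if not 0 <= topic < k:
            raise LengthMismatchError(f"dominant topic {topic} outside 0..{k - 1}")
        by_topic[topic].append(ds.score)
    total = len(doc_scores)
    out = []
    for t in range(k):
        vals = by_topic[t]
        if vals:
            out.append(
                AggregateScore(t, sum(vals) / len(vals), len(vals), len(vals) / total)
            )
        else:
            out.append(AggregateScore(t, None, 0, 0.0 if total else None))
    return out


def term_frequency_report(
    docs: Sequence[NormalizedDocument], top_n: int
) -> list[tuple[str, int]]:
    """Most frequent stems, descending; ties broken lexicographically."""
    counts = Counter(stem for doc in docs for stem in doc.stems())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[: max(top_n, 0)]
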