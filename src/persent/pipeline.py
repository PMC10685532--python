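"""End-to-end pipeline: CSV comments in, analysis artifacts out.

Stages run in a fixed order (normalize -> score -> topics -> per-topic
sentiment -> evaluation -> term frequency) and every artifact is written
atomically (temp file + rename) so a crashed run never leaves a
half-written file. A manifest records the configuration hash and seeds so
identical runs produce identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .errors import CommentFormatError, ConfigError, EmptyDocumentError, EmptyFileError
from .evaluation import (
    MetricsReport,
    compute_metrics,
    confusion,
    evaluate_sections,
    rating_to_label,
    split_corpus,
)
from .lexicon import SentimentLexicon, demo_lexicon, load_lexicon
from .normalization import (
    NormalizationRuleSet,
    NormalizeConfig,
    NormalizedDocument,
    RawComment,
    SECTIONS,
    default_rules,
    normalize_pipeline,
)
from .scoring import (
    DocumentScore,
    NEUTRAL,
    classify,
    score_document,
    term_frequency_report,
    topic_sentiment,
)
from .topics import TopicModelParams, coherence, dominant_topic, fit_lda, select_k, top_words

log = logging.getLogger("persent")


@dataclass
class PipelineConfig:
    input_csv: str | Path
    output_dir: str | Path
    rules_path: str | Path | None = None
    lexicon_path: str | Path | None = None
    neutral_band: float = 0.0
    k: int | None = 6
    k_values: tuple[int, ...] | None = None  # sweep instead of a fixed k
    lda_iters: int = 400
    lda_burn_in: int = 200
    split_ratio: float = 0.9
    top_n_terms: int = 30
    top_n_words: int = 10
    drop_neutral: bool = True
    seed: int = 42
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def _atomic_write(path: Path, payload: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_comments(path: str | Path) -> list[RawComment]:
    """Read and validate a UTF-8 comments CSV (id, section, text, rating, age)."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyFileError(f"{path}: empty file") from exc
    required = {"id", "section", "text"}
    if not required.issubset(frame.columns):
        raise CommentFormatError(
            f"{path}: missing columns {sorted(required - set(frame.columns))}"
        )
    comments: list[RawComment] = []
    bad: list[int] = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            rating = getattr(row, "rating", "")
            age = getattr(row, "age", "")
            comments.append(
                RawComment(
                    id=str(row.id),
                    section=str(row.section),
                    text=str(row.text),
                    rating=int(rating) if str(rating).strip() else None,
                    age=int(age) if str(age).strip() else None,
                )
            )
        except (ValueError, ConfigError) as exc:
            log.warning("row %d rejected: %s", row_no, exc)
            bad.append(row_no)
    if bad:
        raise CommentFormatError(f"{path}: malformed rows {bad}", rows=bad)
    if not comments:
        raise EmptyFileError(f"{path}: no comment rows")
    return comments


def write_comments(comments: Sequence[RawComment], path: str | Path) -> None:
    rows = []
    for c in comments:
        rows.append(
            {
                "id": c.id,
                "section": c.section,
                "text": c.text,
                "rating": "" if c.rating is None else c.rating,
                "age": "" if c.age is None else c.age,
            }
        )
    frame = pd.DataFrame(rows, columns=["id", "section", "text", "rating", "age"])
    _atomic_write(Path(path), frame.to_csv(index=False))


def load_rules(path: str | Path | None) -> NormalizationRuleSet:
    return NormalizationRuleSet.from_json(path) if path else default_rules()


def load_lexicon_or_demo(
    path: str | Path | None, rules: NormalizationRuleSet
) -> SentimentLexicon:
    if path is None:
        return demo_lexicon()
    return load_lexicon(path, rules.shifters, rules.protected_words)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def normalize_corpus(
    comments: Sequence[RawComment],
    rules: NormalizationRuleSet,
    lexicon: SentimentLexicon | None,
    config: NormalizeConfig | None = None,
) -> list[NormalizedDocument]:
    docs = []
    for c in comments:
        try:
            docs.append(normalize_pipeline(c, rules, lexicon, config))
        except EmptyDocumentError:
            log.warning("comment %s produced no sentences; dropped", c.id)
    return docs


def score_corpus(
    docs: Sequence[NormalizedDocument],
    lexicon: SentimentLexicon,
    neutral_band: float = 0.0,
) -> list[DocumentScore]:
    return [score_document(d, lexicon, neutral_band) for d in docs]


def evaluate_corpus(
    scores: Sequence[DocumentScore],
    ratings: dict[str, int],
    split_ratio: float,
    seed: int,
    drop_neutral: bool = True,
) -> dict[str, MetricsReport]:
    """Hold out a test fraction (stratified by true label, mirroring the
    90:10 protocol) and report the six metrics per section on it."""
    rated = [s for s in scores if s.comment_id in ratings]
    ids = [s.comment_id for s in rated]
    labels = [rating_to_label(ratings[s.comment_id]) for s in rated]
    _, test_ids = split_corpus(ids, split_ratio, seed, labels)
    test_set = set(test_ids)
    by_section: dict[str, tuple[list, list, list]] = {s: ([], [], []) for s in SECTIONS}
    for s, lab in zip(rated, labels):
        if s.comment_id not in test_set:
            continue
        if drop_neutral and s.label == NEUTRAL:
            continue
        sec = by_section.setdefault(s.section, ([], [], []))
        sec[0].append(s.score)
        sec[1].append(lab)
        sec[2].append(s.label)
    return evaluate_sections({k: v for k, v in by_section.items() if v[1]})


def overall_metrics(
    scores: Sequence[DocumentScore],
    ratings: dict[str, int],
    drop_neutral: bool = True,
) -> MetricsReport:
    """Whole-corpus metrics (no split), mostly for synthetic-recovery checks."""
    pairs = [
        (s, rating_to_label(ratings[s.comment_id]))
        for s in scores
        if s.comment_id in ratings
    ]
    if drop_neutral:
        pairs = [(s, t) for s, t in pairs if s.label != NEUTRAL]
    cm = confusion([t for _, t in pairs], [s.label for s, _ in pairs])
    return compute_metrics(cm)


# ---------------------------------------------------------------------------
# artifact writers
# ---------------------------------------------------------------------------


def _write_jsonl(path: Path, rows: Sequence[dict]) -> None:
    _atomic_write(path, "".join(json.dumps(r, ensure_ascii=False) + "\n" for r in rows))


def read_normalized(path: str | Path) -> list[NormalizedDocument]:
    with open(path, encoding="utf-8") as fh:
        return [NormalizedDocument.from_dict(json.loads(line)) for line in fh if line.strip()]


def read_scores(path: str | Path) -> list[DocumentScore]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                DocumentScore(
                    d["comment_id"],
                    tuple(),
                    d["score"],
                    d["label"],
                    d.get("section"),
                )
            )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the artifact paths."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rules = load_rules(cfg.rules_path)
    lexicon = load_lexicon_or_demo(cfg.lexicon_path, rules)
    comments = read_comments(cfg.input_csv)

    docs = normalize_corpus(comments, rules, lexicon, cfg.normalize)
    _write_jsonl(outdir / "normalized.jsonl", [d.to_dict() for d in docs])

    scores = score_corpus(docs, lexicon, cfg.neutral_band)
    _write_jsonl(
        outdir / "scores.jsonl",
        [
            {
                "comment_id": s.comment_id,
                "section": s.section,
                "score": s.score,
                "label": s.label,
                "sentence_polarities": [ss.polarity for ss in s.sentence_scores],
            }
            for s in scores
        ],
    )

    params = TopicModelParams(
        k=cfg.k or 6, n_iter=cfg.lda_iters, burn_in=cfg.lda_burn_in, seed=cfg.seed
    )
    coherence_table = None
    if cfg.k_values:
        chosen_k, coherence_table = select_k(docs, cfg.k_values, params)
        params = TopicModelParams(
            k=chosen_k, n_iter=cfg.lda_iters, burn_in=cfg.lda_burn_in, seed=cfg.seed
        )
    result = fit_lda(docs, params)
    dominant = {
        doc.comment_id: dominant_topic(result, i) for i, doc in enumerate(docs)
    }
    topics_payload = {
        "k": result.k,
        "seed": cfg.seed,
        "top_words": {
            str(t): top_words(result, t, cfg.top_n_words) for t in range(result.k)
        },
        "coherence": coherence(result, docs, cfg.top_n_words),
        "coherence_sweep": coherence_table,
        "dominant_topics": dominant,
        "theta": [[float(x) for x in row] for row in result.theta],
    }
    _atomic_write(
        outdir / "topics.json", json.dumps(topics_payload, ensure_ascii=False, indent=1)
    )

    aggregates = topic_sentiment(scores, dominant, result.k)
    buf = []
    for agg in aggregates:
        buf.append(
            {
                "topic": agg.group_key,
                "top_words": " ".join(top_words(result, int(agg.group_key), 5)),
                "reviews": agg.n,
                "review_share": "" if agg.share is None else f"{agg.share:.6f}",
                "sentiment_score": "" if agg.V is None else f"{agg.V:.6f}",
            }
        )
    frame = pd.DataFrame(
        buf, columns=["topic", "top_words", "reviews", "review_share", "sentiment_score"]
    )
    _atomic_write(outdir / "topic_sentiment.csv", frame.to_csv(index=False))

    ratings = {c.id: c.rating for c in comments if c.rating is not None}
    if ratings:
        reports = evaluate_corpus(
            scores, ratings, cfg.split_ratio, cfg.seed, cfg.drop_neutral
        )
        _atomic_write(
            outdir / "metrics.json",
            json.dumps(
                {sec: rep.as_dict() for sec, rep in reports.items()},
                ensure_ascii=False,
                indent=1,
            ),
        )
    else:
        log.info("no ratings present; evaluation stage skipped")

    freq = term_frequency_report(docs, cfg.top_n_terms)
    writer_buf = "term,count\n" + "".join(f"{t},{c}\n" for t, c in freq)
    _atomic_write(outdir / "frequency.csv", writer_buf)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "input": str(cfg.input_csv),
                    "rules": str(cfg.rules_path),
                    "lexicon": str(cfg.lexicon_path),
                    "neutral_band": cfg.neutral_band,
                    "k": cfg.k,
                    "k_values": cfg.k_values,
                    "lda_iters": cfg.lda_iters,
                    "lda_burn_in": cfg.lda_burn_in,
                    "split_ratio": cfg.split_ratio,
                    "seed": cfg.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "n_comments": len(comments),
        "n_documents": len(docs),
        "artifacts": [
            "normalized.jsonl",
            "scores.jsonl",
            "topics.json",
            "topic_sentiment.csv",
            "metrics.json" if ratings else None,
            "frequency.csv",
        ],
    }
    _atomic_write(outdir / "manifest.json", json.dumps(manifest, indent=1))
    return {
        p.name: p
        for p in outdir.iterdir()
        if p.suffix in {".json", ".jsonl", ".csv"}
    }
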