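"""Sentiment lexicon with integer strengths in -5..+5 and negation shifters.

The scoring strategy assigns each term an integer influence from -5
(strongly negative) to +5 (strongly positive); zero is forbidden so that
"absent from the lexicon" is the only way to be neutral. Negation is
rule-based: a token beginning with one of the shifter particles
(``ن``, ``نا``, ``ضد``) whose remainder is a known word is treated as the
negated remainder, and its strength is sign-inverted at lookup time.
Words that merely *look* negated (``ناراحت``, ``نگران``) are listed as
protected and never stripped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import DuplicateTermError, LexiconFormatError, StrengthRangeError
from .normalization import Token

HEADER = ("term", "strength")


@dataclass
class SentimentLexicon:
    entries: dict[str, int] = field(default_factory=dict)
    shifters: tuple[str, ...] = ("نا", "ن", "ضد")
    protected_words: frozenset[str] = frozenset()

    def __post_init__(self):
        self.shifters = tuple(sorted(self.shifters, key=len, reverse=True))
        self.protected_words = frozenset(self.protected_words)
        if not self.shifters:
            raise LexiconFormatError("shifter list must be non-empty")
        for term, s in self.entries.items():
            _validate_strength(term, s)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def positives(self) -> list[str]:
        return [t for t, s in self.entries.items() if s > 0]

    def negatives(self) -> list[str]:
        return [t for t, s in self.entries.items() if s < 0]


def _validate_strength(term: str, strength: int) -> None:
    if not isinstance(strength, int) or isinstance(strength, bool):
        raise LexiconFormatError(f"{term!r}: strength must be an integer")
    if strength == 0 or abs(strength) > 5:
        raise StrengthRangeError(
            f"{term!r}: strength {strength} outside {{-5..-1}} u {{+1..+5}}"
        )


def load_lexicon(
    path: str | Path,
    shifters: Iterable[str] = ("نا", "ن", "ضد"),
    protected_words: Iterable[str] = (),
) -> SentimentLexicon:
    """Read a UTF-8 TSV with header ``term<TAB>strength``."""
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != HEADER:
            raise LexiconFormatError(f"{path}: expected header 'term\\tstrength'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise LexiconFormatError(f"{path}:{lineno}: expected 2 columns")
            term = row[0].strip()
            try:
                strength = int(row[1])
            except ValueError as exc:
                raise LexiconFormatError(
                    f"{path}:{lineno}: non-integer strength {row[1]!r}"
                ) from exc
            _validate_strength(term, strength)
            if term in entries:
                raise DuplicateTermError(f"{path}:{lineno}: duplicate term {term!r}")
            entries[term] = strength
    return SentimentLexicon(entries, tuple(shifters), frozenset(protected_words))


def save_lexicon(lexicon: SentimentLexicon, path: str | Path) -> None:
    """Write the lexicon as TSV in deterministic sorted term order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HEADER)
        for term in sorted(lexicon.entries):
            writer.writerow([term, lexicon.entries[term]])


def demo_lexicon() -> SentimentLexicon:
    """Small hand-curated Persian lexicon bundled for demos and tests."""
    from .normalization import default_rules

    rules = default_rules()
    with resources.as_file(resources.files("persent.data") / "demo_lexicon.tsv") as p:
        return load_lexicon(p, rules.shifters, rules.protected_words)


def detect_negation(
    token: str,
    lexicon: SentimentLexicon,
    vocabulary: Iterable[str] | None = None,
) -> tuple[str, bool]:
    """Strip a leading shifter when the remainder is a known word.

    Returns ``(base, negated)``. Protected words and tokens whose stripped
    remainder is unknown to both the lexicon and the optional vocabulary
    are never flagged (guards against false shifts such as person names).
    """
    if token in lexicon.protected_words:
        return token, False
    vocab = set(vocabulary) if vocabulary else set()
    for shifter in lexicon.shifters:  # longest first
        if token.startswith(shifter):
            base = token[len(shifter):].lstrip("‌")
            if base and (base in lexicon.entries or base in vocab):
                return base, True
    return token, False


def lookup(lexicon: SentimentLexicon, token: Token) -> int | None:
    """Strength of a token's stem; sign-inverted when negated; None if absent."""
    strength = lexicon.entries.get(token.stem)
    if strength is None:
        return None
    return -strength if token.negated else strength
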