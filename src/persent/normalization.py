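"""Rule-based normalization of Persian free-text comments.

Persian web text mixes Arabic code points with Persian ones (``ي``/``ی``,
``ك``/``ک``), drops the madda from word-initial ``آ``, detaches suffixes,
writes verbal prefixes with a full space instead of the zero-width
non-joiner, stretches words with the kashida, and spells many words in
several accepted variants. Every transformation here is driven by an
explicit, serializable :class:`NormalizationRuleSet` so the behaviour is a
property of the rules, not of the code.

The canonical processing order is fixed by :func:`normalize_pipeline`:
character unification -> spacing -> affix reattachment -> spelling
unification -> sentence splitting -> punctuation removal -> tokenization
-> (optional spell check) -> negation detection -> stopword removal ->
stemming. Sentence terminators are consumed by the splitter *before*
punctuation is stripped, so splitting always sees its delimiters.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .errors import ConfigError, EmptyDocumentError

ZWNJ = "‌"  # half-space (pseudo-space)
KASHIDA = "ـ"
SENTENCE_TERMINATORS = ".؟?!؛\n"

SECTIONS = ("healthcare_services", "general_services", "life_expectancy")

# characters that may legally appear inside a Persian word
_WORD_CHAR = r"[^\W\d_]|[‌ـ]"
_BOUNDARY_L = rf"(?<!{_WORD_CHAR})"
_BOUNDARY_R = rf"(?!{_WORD_CHAR})"


@dataclass(frozen=True)
class RawComment:
    """One patient comment as collected from a feedback form."""

    id: str
    section: str
    text: str
    rating: int | None = None
    age: int | None = None

    def __post_init__(self):
        if self.section not in SECTIONS:
            raise ConfigError(f"unknown section {self.section!r}")
        if not self.text.strip():
            raise ConfigError(f"comment {self.id}: empty text")
        if self.rating is not None and self.rating not in (1, 2, 3, 4, 5):
            raise ConfigError(f"comment {self.id}: rating {self.rating} not in 1..5")


@dataclass(frozen=True)
class Token:
    surface: str  # normalized surface, shifter already stripped when negated
    stem: str
    negated: bool = False


@dataclass(frozen=True)
class Sentence:
    index: int
    tokens: tuple[Token, ...]


@dataclass(frozen=True)
class NormalizedDocument:
    comment_id: str
    sentences: tuple[Sentence, ...]
    section: str | None = None

    def stems(self) -> list[str]:
        return [t.stem for s in self.sentences for t in s.tokens]

    def surfaces(self) -> list[str]:
        return [t.surface for s in self.sentences for t in s.tokens]

    def to_dict(self) -> dict:
        return {
            "comment_id": self.comment_id,
            "section": self.section,
            "sentences": [
                [[t.surface, t.stem, int(t.negated)] for t in s.tokens]
                for s in self.sentences
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizedDocument":
        sentences = tuple(
            Sentence(i, tuple(Token(s, st, bool(n)) for s, st, n in toks))
            for i, toks in enumerate(d["sentences"])
        )
        return cls(d["comment_id"], sentences, d.get("section"))


@dataclass
class NormalizationRuleSet:
    """Declarative rules driving every normalization operation.

    ``char_map`` holds both single-character unifications (Arabic ->
    Persian forms) and whole-word entries used to restore a dropped
    word-initial ``آ`` (e.g. ``اب -> آب``); the general "prepend madda to
    every alef-initial word" rule would corrupt valid words, so
    restoration is list-driven.
    """

    char_map: dict[str, str] = field(default_factory=dict)
    spelling_variants: dict[str, str] = field(default_factory=dict)
    suffixes: tuple[str, ...] = ()
    prefixes: tuple[str, ...] = ()
    stopwords: frozenset[str] = frozenset()
    punctuation: frozenset[str] = frozenset()
    elongation_chars: frozenset[str] = frozenset({KASHIDA})
    shifters: tuple[str, ...] = ("نا", "ن", "ضد")
    protected_words: frozenset[str] = frozenset()

    def __post_init__(self):
        self.suffixes = tuple(self.suffixes)
        self.prefixes = tuple(self.prefixes)
        self.stopwords = frozenset(self.stopwords)
        self.punctuation = frozenset(self.punctuation)
        self.elongation_chars = frozenset(self.elongation_chars)
        self.shifters = tuple(self.shifters)
        self.protected_words = frozenset(self.protected_words)
        single = {k for k in self.char_map if len(k) == 1}
        for k, v in self.char_map.items():
            if any(c in single for c in v) or v in self.char_map:
                raise ConfigError(f"char_map not idempotent at {k!r} -> {v!r}")
        for k, v in self.spelling_variants.items():
            if v in self.spelling_variants:
                raise ConfigError(
                    f"spelling variant target {v!r} is itself a variant key"
                )

    # -- compiled machinery (derived, cached) --------------------------------

    @cached_property
    def _char_table(self) -> dict[int, str]:
        return {ord(k): v for k, v in self.char_map.items() if len(k) == 1}

    @cached_property
    def _word_map(self) -> dict[str, str]:
        return {k: v for k, v in self.char_map.items() if len(k) > 1}

    @cached_property
    def _word_map_re(self) -> re.Pattern | None:
        return _word_regex(self._word_map)

    @cached_property
    def _spelling_re(self) -> re.Pattern | None:
        return _word_regex(self.spelling_variants)

    @cached_property
    def restorable_alef_words(self) -> frozenset[str]:
        """Canonical forms whose alef-spelled variant the rules repair."""
        return frozenset(self._word_map.values())

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationRuleSet":
        path = Path(path)
        raw = json.loads(path.read_text(encoding="utf-8"))
        stopwords: set[str] = set(raw.pop("stopwords", []))
        stop_file = raw.pop("stopwords_file", None)
        if stop_file:
            stop_path = path.parent / stop_file
            stopwords |= {
                w.strip() for w in stop_path.read_text(encoding="utf-8").splitlines() if w.strip()
            }
        return cls(
            char_map=raw.get("char_map", {}),
            spelling_variants=raw.get("spelling_variants", {}),
            suffixes=tuple(raw.get("suffixes", ())),
            prefixes=tuple(raw.get("prefixes", ())),
            stopwords=frozenset(stopwords),
            punctuation=frozenset(raw.get("punctuation", ())),
            elongation_chars=frozenset(raw.get("elongation_chars", (KASHIDA,))),
            shifters=tuple(raw.get("shifters", ("نا", "ن", "ضد"))),
            protected_words=frozenset(raw.get("protected_words", ())),
        )


def _word_regex(mapping: dict[str, str]) -> re.Pattern | None:
    if not mapping:
        return None
    keys = sorted(mapping, key=len, reverse=True)
    alt = "|".join(re.escape(k) for k in keys)
    return re.compile(rf"{_BOUNDARY_L}(?:{alt}){_BOUNDARY_R}")


def default_rules() -> NormalizationRuleSet:
    """The rule set bundled with the package."""
    with resources.as_file(resources.files("persent.data") / "rules.json") as p:
        return NormalizationRuleSet.from_json(p)


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------


def normalize_characters(text: str, rules: NormalizationRuleSet) -> str:
    """Unify character encodings (NFC, Arabic->Persian forms, آ restoration)."""
    text = unicodedata.normalize("NFC", text)
    text = text.translate(rules._char_table)
    pattern = rules._word_map_re
    if pattern is not None:
        text = pattern.sub(lambda m: rules._word_map[m.group(0)], text)
    return text


def normalize_spacing(text: str, rules: NormalizationRuleSet) -> str:
    """Collapse runs of spaces/tabs, trim, and drop elongation characters.

    Newlines are preserved (they double as sentence terminators); stray
    half-spaces next to a real space are redundant and removed.
    """
    for ch in rules.elongation_chars:
        text = text.replace(ch, "")
    text = re.sub(r"[ \t ]+", " ", text)
    text = re.sub(rf"{ZWNJ}+", ZWNJ, text)
    text = re.sub(rf"{ZWNJ}*([ \n]){ZWNJ}*", r"\1", text)
    text = re.sub(r" ?\n ?", "\n", text)
    return text.strip(f" {ZWNJ}")


def _split_trailing_punct(token: str, rules: NormalizationRuleSet) -> tuple[str, str]:
    punct = set(rules.punctuation) | set(SENTENCE_TERMINATORS)
    i = len(token)
    while i > 0 and token[i - 1] in punct:
        i -= 1
    return token[:i], token[i:]


def normalize_affixes(text: str, rules: NormalizationRuleSet) -> str:
    """Reattach detached suffixes and join listed prefixes with a half-space.

    ``مناسب تر`` becomes ``مناسبتر`` (suffix attached directly) and
    ``می رود`` becomes ``می‌رود`` (prefix joined by ZWNJ). A token whose
    core carries trailing punctuation marks a sentence boundary and is
    never merged with what follows.
    """
    if not text:
        return text
    out: list[str] = []
    tokens = text.split(" ")
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        core, trail = _split_trailing_punct(tok, rules)
        nxt = tokens[i + 1] if i + 1 < len(tokens) else None
        if nxt is not None and core and not trail:
            ncore, ntrail = _split_trailing_punct(nxt, rules)
            if ncore in rules.suffixes:
                out.append(core + ncore + ntrail)
                i += 2
                continue
            if core in rules.prefixes and ncore:
                out.append(core + ZWNJ + nxt)
                i += 2
                continue
        out.append(tok)
        i += 1
    return " ".join(out)


def normalize_spelling(text: str, rules: NormalizationRuleSet) -> str:
    """Replace whole-word spelling/compound variants by their canonical form."""
    pattern = rules._spelling_re
    if pattern is None:
        return text
    return pattern.sub(lambda m: rules.spelling_variants[m.group(0)], text)


def remove_punctuation(text: str, rules: NormalizationRuleSet) -> str:
    table = {ord(c): None for c in rules.punctuation}
    return text.translate(table)


def split_sentences(text: str) -> list[str]:
    """Partition text at sentence terminators; empty fragments are dropped."""
    parts = re.split(f"[{re.escape(SENTENCE_TERMINATORS)}]+", text)
    return [p.strip() for p in parts if p.strip()]


def tokenize(sentence_text: str) -> list[str]:
    """Whitespace tokenization; the half-space never splits a token."""
    return sentence_text.split()


def remove_stopwords(tokens: Sequence[str], rules: NormalizationRuleSet) -> list[str]:
    return [t for t in tokens if t not in rules.stopwords]


def stem(token: str, suffixes: Sequence[str]) -> str:
    """Strip the longest listed suffix, at most twice; never empties a token."""
    ordered = sorted(suffixes, key=len, reverse=True)
    for _ in range(2):
        for sfx in ordered:
            if token.endswith(sfx) and len(token) > len(sfx):
                token = token[: -len(sfx)].rstrip(ZWNJ) or token
                break
        else:
            break
    return token


def _within_edit1(a: str, b: str) -> bool:
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # one substitution
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is one longer: one insertion
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def spell_check(tokens: Sequence[str], vocabulary: Iterable[str]) -> list[str]:
    """Conservative corrector: replace an out-of-vocabulary token only when
    exactly one vocabulary word lies at edit distance 1."""
    vocab = set(vocabulary)
    out = []
    for tok in tokens:
        if tok in vocab:
            out.append(tok)
            continue
        cands = [w for w in vocab if _within_edit1(tok, w)]
        out.append(cands[0] if len(cands) == 1 else tok)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class NormalizeConfig:
    remove_stopwords: bool = True
    stem: bool = True
    spell_check: bool = False
    detect_negation: bool = True
    vocabulary: frozenset[str] | None = None  # extra known words for negation/spelling
    stemmer: Callable[[str], str] | None = None  # overrides suffix stripping


def normalize_pipeline(
    comment: RawComment,
    rules: NormalizationRuleSet,
    lexicon=None,
    config: NormalizeConfig | None = None,
) -> NormalizedDocument:
    """Run the full normalization cascade on one comment.

    Raises :class:`EmptyDocumentError` when nothing survives.
    """
    from .lexicon import detect_negation  # local import avoids a cycle

    cfg = config or NormalizeConfig()
    text = normalize_characters(comment.text, rules)
    text = normalize_spacing(text, rules)
    text = normalize_affixes(text, rules)
    text = normalize_spelling(text, rules)
    stemmer = cfg.stemmer or (lambda t: stem(t, rules.suffixes))

    sentences: list[Sentence] = []
    for frag in split_sentences(text):
        frag = remove_punctuation(frag, rules)
        toks = tokenize(frag)
        if cfg.spell_check and cfg.vocabulary:
            toks = spell_check(toks, cfg.vocabulary)
        built: list[Token] = []
        for surface in toks:
            negated = False
            base = surface
            if cfg.detect_negation and lexicon is not None:
                base, negated = detect_negation(surface, lexicon, cfg.vocabulary)
            if cfg.remove_stopwords and base in rules.stopwords:
                continue
            built.append(Token(base, stemmer(base) if cfg.stem else base, negated))
        if built:
            sentences.append(Sentence(len(sentences), tuple(built)))
    if not sentences:
        raise EmptyDocumentError(f"comment {comment.id}: no sentence survived")
    return NormalizedDocument(comment.id, tuple(sentences), comment.section)
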