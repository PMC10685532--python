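"""Synthetic Persian-like feedback corpora with known ground truth.

The real hospital-feedback corpus this toolkit targets is private, so the
generator emits corpora that emulate its published surface statistics
(about 41 words and 4 sentences per comment), its 1-5 satisfaction
ratings, a planted topic structure, lexicon terms of known strength with
occasional negation, and the surface noise classes the normalizer models
(Arabic character forms, dropped madda, stray spaces, detached suffixes,
split prefixes, kashida elongation, spelling variants).

All guarantees are lexicon-relative: text is a bag of real Persian words,
not fluent prose. Corruption is inverse to normalization by construction,
so ``normalize(corrupt(x)) == normalize(x)`` for every modeled noise
class; each token receives at most one noise class per draw to keep that
round trip exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .errors import ConfigError
from .lexicon import SentimentLexicon, detect_negation
from .normalization import ZWNJ, KASHIDA, NormalizationRuleSet, RawComment, SECTIONS, default_rules

# satisfaction skews positive in the emulated feedback-form setting
RATING_PROBS = (0.08, 0.12, 0.15, 0.30, 0.35)
# age mix: under 30 / 30-60 / over 60
AGE_BIN_PROBS = (0.089, 0.636, 0.275)
AGE_BINS = ((18, 29), (30, 60), (61, 90))

# intended per-sentence polarity magnitude for each rating; the resulting
# document score (polarity/5) lands in disjoint bands so the binary label
# is recoverable by design
RATING_POLARITY_CHOICES = {
    5: (4, 5),
    4: (2, 3),
    3: (1,),
    2: (-1, -2),
    1: (-3, -4, -5),
}

_POS_POOL = (
    "خوب", "راضی", "خوشحال", "صمیمی", "مهربان", "عالی", "تمیز", "مرتب",
    "سریع", "دلسوز", "محترم", "خوشمزه", "مفید", "امید", "راحت", "شاد",
    "قوی", "دقیق", "منظم", "امن", "خندان", "گرم", "خوشایند", "مودب", "مناسب",
)
_NEG_POOL = (
    "بد", "کثیف", "شلوغ", "گران", "ناراحت", "عصبانی", "نگران", "ضعیف",
    "کند", "سرد", "خراب", "افتضاح", "ناامید", "دیر", "تلخ", "ترسناک",
    "سخت", "طولانی", "دردناک", "غمگین", "بی‌نظم", "وحشتناک", "ضایع", "نامناسب",
)
_PROTECTED = ("ناراحت", "ناامید", "نگران", "ناهار", "نامناسب")
_SAFE_STOPWORDS = ("و", "در", "به", "از", "که", "با", "برای", "هم", "تا")

_LETTERS = "بپتجچحخدرزسشصطعفقکگلمهوی"


@dataclass(frozen=True)
class NoiseRates:
    """Per-token (or per-gap) application probabilities for each noise class."""

    arabic_chars: float = 0.05
    extra_spaces: float = 0.10
    detached_suffix: float = 0.05
    split_prefix: float = 0.05
    elongation: float = 0.05
    spelling_variant: float = 0.05
    alef_drop: float = 0.05

    def all_zero(self) -> bool:
        return all(v == 0 for v in self.__dict__.values())


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 200
    sentences_per_doc_mean: float = 3.9
    words_per_doc_mean: float = 41.3
    k_true: int = 3
    topic_word_concentration: float = 0.5
    doc_topic_concentration: float = 0.2
    sentiment_injection_rate: float = 0.5
    negation_rate: float = 0.1
    out_of_lexicon_rate: float = 0.0
    stopword_rate: float = 0.15
    surface_noise_rates: NoiseRates = field(default_factory=NoiseRates)
    section_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self):
        rates = (
            self.sentiment_injection_rate,
            self.negation_rate,
            self.out_of_lexicon_rate,
            self.stopword_rate,
            *self.surface_noise_rates.__dict__.values(),
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ConfigError("all rates must lie in [0, 1]")
        if self.sentences_per_doc_mean <= 0 or self.words_per_doc_mean <= 0:
            raise ConfigError("means must be positive")
        if self.k_true < 1:
            raise ConfigError("k_true must be >= 1")
        if abs(sum(self.section_mix) - 1) > 1e-9:
            raise ConfigError("section_mix must sum to 1")


@dataclass(frozen=True)
class CommentTruth:
    comment_id: str
    section: str
    rating: int
    label: str
    dominant_topic: int
    age: int
    clean_text: str
    clean_tokens: tuple[str, ...]
    intended_polarities: tuple[int, ...]  # per sentence, 0 = neutral sentence
    injected: tuple[dict, ...]  # term surface, base, strength, negated, in_lexicon


@dataclass(frozen=True)
class GroundTruth:
    records: tuple[CommentTruth, ...]
    phi_true: np.ndarray  # k_true x V_content over content_vocab
    theta_true: np.ndarray  # D x k_true
    content_vocab: tuple[str, ...]
    topic_blocks: tuple[tuple[str, ...], ...]

    def labels(self) -> dict[str, str]:
        return {r.comment_id: r.label for r in self.records}

    def dominant_topics(self) -> dict[str, int]:
        return {r.comment_id: r.dominant_topic for r in self.records}


def content_words() -> tuple[str, ...]:
    """The bundled neutral Persian word list used for document content."""
    with resources.as_file(resources.files("persent.data") / "words.txt") as p:
        words = [w.strip() for w in p.read_text(encoding="utf-8").splitlines()]
    return tuple(w for w in words if w)


def _pseudo_word(rng: np.random.Generator, taken: set[str]) -> str:
    # 'گ'-initial so the result can never start with a shifter particle
    while True:
        n = int(rng.integers(3, 6))
        w = "گ" + "".join(rng.choice(list(_LETTERS), size=n))
        if w not in taken:
            taken.add(w)
            return w


def generate_lexicon(n_terms: int, seed: int) -> SentimentLexicon:
    """Balanced synthetic lexicon; magnitudes cycle 1..5 so every strength
    level on each side is represented once n_terms >= 10."""
    if n_terms < 2:
        raise ConfigError("n_terms must be >= 2")
    rng = np.random.default_rng(seed)
    n_pos = (n_terms + 1) // 2
    n_neg = n_terms - n_pos
    taken = set(_POS_POOL) | set(_NEG_POOL) | set(content_words())
    entries: dict[str, int] = {}
    for pool, count, sign in ((_POS_POOL, n_pos, 1), (_NEG_POOL, n_neg, -1)):
        terms = list(rng.permutation(pool))
        while len(terms) < count:
            terms.append(_pseudo_word(rng, taken))
        mags = [(i % 5) + 1 for i in range(count)]
        rng.shuffle(mags)
        for term, mag in zip(terms[:count], mags):
            entries[term] = sign * mag
    return SentimentLexicon(entries, ("نا", "ن", "ضد"), frozenset(_PROTECTED))


# ---------------------------------------------------------------------------
# surface corruption
# ---------------------------------------------------------------------------


def _strip_trail(token: str) -> tuple[str, str]:
    i = len(token)
    while i > 0 and token[i - 1] in ".!؟?؛،":
        i -= 1
    return token[:i], token[i:]


def _corrupt_token(core: str, rates: NoiseRates, rules: NormalizationRuleSet,
                   rng: np.random.Generator) -> str:
    alef_variants = {v: k for k, v in rules.char_map.items() if len(k) > 1}
    spelling_inv: dict[str, list[str]] = {}
    for variant, canonical in rules.spelling_variants.items():
        spelling_inv.setdefault(canonical, []).append(variant)

    eligible: list[str] = []
    if rates.arabic_chars and ("ی" in core or "ک" in core):
        eligible.append("arabic")
    if rates.alef_drop and core in alef_variants:
        eligible.append("alef")
    if rates.spelling_variant and core in spelling_inv:
        eligible.append("spelling")
    if rates.split_prefix and any(
        core.startswith(p + ZWNJ) and len(core) > len(p) + 1 for p in rules.prefixes
    ):
        eligible.append("prefix")
    if rates.detached_suffix and any(
        core.endswith(s) and len(core) > len(s) and not core[: -len(s)].endswith(ZWNJ)
        for s in rules.suffixes
    ):
        eligible.append("suffix")
    if rates.elongation and len(core) >= 2 and ZWNJ not in core:
        eligible.append("elong")

    fired = [
        c for c in eligible
        if rng.random() < getattr(rates, {
            "arabic": "arabic_chars", "alef": "alef_drop", "spelling": "spelling_variant",
            "prefix": "split_prefix", "suffix": "detached_suffix", "elong": "elongation",
        }[c])
    ]
    if not fired:
        return core
    cls = fired[int(rng.integers(len(fired)))]
    if cls == "arabic":
        return core.replace("ی", "ي").replace("ک", "ك")
    if cls == "alef":
        return alef_variants[core]
    if cls == "spelling":
        variants = spelling_inv[core]
        return variants[int(rng.integers(len(variants)))]
    if cls == "prefix":
        for p in sorted(rules.prefixes, key=len, reverse=True):
            if core.startswith(p + ZWNJ):
                return p + " " + core[len(p) + 1:]
    if cls == "suffix":
        for s in sorted(rules.suffixes, key=len, reverse=True):
            if core.endswith(s) and len(core) > len(s) and not core[: -len(s)].endswith(ZWNJ):
                return core[: -len(s)] + " " + s
    if cls == "elong":
        pos = int(rng.integers(1, len(core)))
        return core[:pos] + KASHIDA * int(rng.integers(1, 5)) + core[pos:]
    return core


def corrupt_surface(
    text: str,
    config: GeneratorConfig,
    seed: int,
    rules: NormalizationRuleSet | None = None,
) -> str:
    """Apply the modeled surface-noise classes to clean normalized text."""
    rules = rules or default_rules()
    rates = config.surface_noise_rates
    rng = np.random.default_rng(seed)
    if rates.all_zero():
        return text
    pieces: list[str] = []
    for token in text.split(" "):
        core, trail = _strip_trail(token)
        if core:
            core = _corrupt_token(core, rates, rules, rng)
        pieces.append(core + trail)
    gaps = []
    for _ in range(len(pieces) - 1):
        if rng.random() < rates.extra_spaces:
            gaps.append([" " * int(rng.integers(2, 4)), " \t ", "  "][int(rng.integers(3))])
        else:
            gaps.append(" ")
    out = pieces[0] if pieces else ""
    for gap, piece in zip(gaps, pieces[1:]):
        out = out + gap + piece
    if rng.random() < rates.extra_spaces:
        out = " " + out
    if rng.random() < rates.extra_spaces:
        out = out + " "
    return out


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def _negation_candidates(lexicon: SentimentLexicon) -> dict[int, list[tuple[str, str]]]:
    """For each intended polarity p, the (written form, base) pairs whose
    detected negation realizes p exactly."""
    out: dict[int, list[tuple[str, str]]] = {}
    for base, s in sorted(lexicon.entries.items()):
        if any(base.startswith(sh) for sh in lexicon.shifters):
            continue
        written = "ن" + base
        if written in lexicon.entries or written in lexicon.protected_words:
            continue
        got_base, negated = detect_negation(written, lexicon)
        if negated and got_base == base:
            out.setdefault(-s, []).append((written, base))
    return out


def _by_strength(lexicon: SentimentLexicon) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for term, s in sorted(lexicon.entries.items()):
        out.setdefault(s, []).append(term)
    return out


def generate_corpus(
    config: GeneratorConfig,
    lexicon: SentimentLexicon,
    rules: NormalizationRuleSet | None = None,
) -> tuple[list[RawComment], GroundTruth]:
    """Generate raw comments plus full ground truth.

    Sentiment is injected one term per chosen sentence with a strength
    whose document-level score lands in the rating's band; a comment uses
    negated writing (shifter-attached forms of opposite-sign bases) with
    probability ``negation_rate``, in every injected sentence, emulating
    authors who phrase their judgement through negation.
    """
    rules = rules or default_rules()
    rng = np.random.default_rng(config.seed)

    vocab = [
        w for w in content_words()
        if w not in lexicon.entries and w not in rules.stopwords
    ]
    if len(vocab) < 2 * config.k_true:
        raise ConfigError("content vocabulary too small for k_true topics")
    order = rng.permutation(len(vocab))
    blocks: list[list[str]] = [[] for _ in range(config.k_true)]
    for pos, idx in enumerate(order):
        blocks[pos % config.k_true].append(vocab[idx])
    phi_true = np.zeros((config.k_true, len(vocab)))
    windex = {w: i for i, w in enumerate(vocab)}
    for t, block in enumerate(blocks):
        weights = rng.dirichlet([config.topic_word_concentration] * len(block))
        for w, p in zip(block, weights):
            phi_true[t, windex[w]] = p

    by_strength = _by_strength(lexicon)
    neg_candidates = _negation_candidates(lexicon)
    taken = set(vocab) | set(lexicon.entries)
    words_per_sentence = config.words_per_doc_mean / config.sentences_per_doc_mean

    comments: list[RawComment] = []
    records: list[CommentTruth] = []
    theta_true = np.zeros((config.n_docs, config.k_true))
    for d in range(config.n_docs):
        cid = f"c{d:05d}"
        section = SECTIONS[rng.choice(3, p=config.section_mix)]
        rating = int(rng.choice(5, p=RATING_PROBS)) + 1
        label = "positive" if rating >= 3 else "negative"
        bin_idx = rng.choice(3, p=AGE_BIN_PROBS)
        age = int(rng.integers(AGE_BINS[bin_idx][0], AGE_BINS[bin_idx][1] + 1))
        theta = rng.dirichlet([config.doc_topic_concentration] * config.k_true)
        theta_true[d] = theta
        dom = int(np.argmax(theta))

        n_sent = max(1, int(rng.poisson(config.sentences_per_doc_mean)))
        inject = [rng.random() < config.sentiment_injection_rate for _ in range(n_sent)]
        if not any(inject):
            inject[int(rng.integers(n_sent))] = True
        negated_doc = rng.random() < config.negation_rate
        choices = RATING_POLARITY_CHOICES[rating]
        p_doc = int(choices[int(rng.integers(len(choices)))])

        sentences: list[list[str]] = []
        intended: list[int] = []
        injected_info: list[dict] = []
        for s_idx in range(n_sent):
            length = max(2, int(rng.poisson(words_per_sentence)))
            toks: list[str] = []
            for _ in range(length - (1 if inject[s_idx] else 0)):
                if rng.random() < config.stopword_rate:
                    toks.append(_SAFE_STOPWORDS[int(rng.integers(len(_SAFE_STOPWORDS)))])
                else:
                    z = rng.choice(config.k_true, p=theta)
                    toks.append(vocab[rng.choice(len(vocab), p=phi_true[z])])
            if inject[s_idx]:
                use_neg = negated_doc and p_doc in neg_candidates
                if use_neg:
                    cands = neg_candidates[p_doc]
                    written, base = cands[int(rng.integers(len(cands)))]
                    strength = p_doc
                else:
                    cands2 = by_strength.get(p_doc)
                    if not cands2:
                        raise ConfigError(
                            f"lexicon has no term of strength {p_doc}; "
                            "use generate_lexicon or a lexicon covering 1..5"
                        )
                    written = base = cands2[int(rng.integers(len(cands2)))]
                    strength = p_doc
                in_lex = True
                if rng.random() < config.out_of_lexicon_rate:
                    written = base = _pseudo_word(rng, taken)
                    in_lex = False
                toks.insert(int(rng.integers(len(toks) + 1)), written)
                injected_info.append(
                    {"sentence": s_idx, "surface": written, "base": base,
                     "strength": strength, "negated": bool(use_neg and in_lex),
                     "in_lexicon": in_lex}
                )
                intended.append(p_doc if in_lex else 0)
            else:
                intended.append(0)
            sentences.append(toks)

        clean_text = " ".join(" ".join(toks) + "." for toks in sentences)
        clean_tokens = tuple(t for toks in sentences for t in toks)
        corrupt_seed = int(rng.integers(0, 2**31 - 1))
        text = corrupt_surface(clean_text, config, corrupt_seed, rules)
        comments.append(RawComment(cid, section, text, rating, age))
        records.append(
            CommentTruth(cid, section, rating, label, dom, age, clean_text,
                         clean_tokens, tuple(intended), tuple(injected_info))
        )

    truth = GroundTruth(
        tuple(records), phi_true, theta_true, tuple(vocab),
        tuple(tuple(b) for b in blocks),
    )
    return comments, truth


def topic_recovery_metrics(
    result,
    truth: GroundTruth,
    rules: NormalizationRuleSet | None = None,
    top_n: int = 10,
) -> dict:
    """Compare a fitted topic model against the generator's planted topics.

    True topic-word distributions are re-expressed over stems (the model's
    vocabulary), matched one-to-one to estimated topics by maximal cosine
    similarity, and scored by top-word overlap, total-variation distance,
    and dominant-topic accuracy.
    """
    from scipy.optimize import linear_sum_assignment

    from .normalization import stem as stem_fn
    from .topics import dominant_topic, top_words

    rules = rules or default_rules()
    k = truth.phi_true.shape[0]
    vidx = {w: i for i, w in enumerate(result.vocabulary)}
    true_vecs = np.zeros((k, len(result.vocabulary)))
    true_tops: list[list[str]] = []
    for t in range(k):
        probs: dict[str, float] = {}
        for w, p in zip(truth.content_vocab, truth.phi_true[t]):
            if p > 0:
                s = stem_fn(w, rules.suffixes)
                probs[s] = probs.get(s, 0.0) + p
        true_tops.append(
            [w for w, _ in sorted(probs.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]]
        )
        for w, p in probs.items():
            if w in vidx:
                true_vecs[t, vidx[w]] = p
    cost = np.zeros((k, k))
    for t in range(k):
        for j in range(k):
            denom = np.linalg.norm(true_vecs[t]) * np.linalg.norm(result.phi[j])
            cost[t, j] = -float(true_vecs[t] @ result.phi[j]) / denom
    rows, cols = linear_sum_assignment(cost)
    overlaps, tv = [], []
    est_to_true = {}
    for t, j in zip(rows, cols):
        est_to_true[int(j)] = int(t)
        est_top = top_words(result, int(j), top_n)
        overlaps.append(len(set(est_top) & set(true_tops[t])) / top_n)
        tv.append(0.5 * float(np.abs(true_vecs[t] - result.phi[j]).sum()))
    true_dom = {r.comment_id: r.dominant_topic for r in truth.records}
    hits = [
        est_to_true[dominant_topic(result, i)] == true_dom[cid]
        for i, cid in enumerate(result.doc_ids)
        if cid in true_dom
    ]
    return {
        "top_word_overlap": overlaps,
        "tv_distance": tv,
        "dominant_topic_accuracy": float(np.mean(hits)),
        "topic_mapping": est_to_true,
    }


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """The same study conditions with all surface noise switched off."""
    return replace(config, surface_noise_rates=NoiseRates(0, 0, 0, 0, 0, 0, 0))
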