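# Methods

This note documents the models and procedures implemented in `persent`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not
demonstrate.

## Normalization

Normalization is a fixed cascade: character unification → spacing →
affix reattachment → spelling unification → sentence splitting →
punctuation removal → tokenization → optional spell check → negation
detection → stopword removal → stemming. Two ordering choices deserve
comment:

- **Split before stripping punctuation.** Sentence terminators
  (`.", "؟", "?", "!", "؛`, newline) are consumed by the splitter, and
  punctuation is deleted per fragment afterwards; deleting punctuation
  first would destroy the split points.
- **Characters before spacing before affixes.** Affix and spelling rules
  match canonical characters, so character unification must run first;
  affix reattachment operates on space-separated tokens, so spacing must
  already be collapsed.

The madda restoration (`اب` → `آب`) is driven by an explicit word list
inside the character map rather than a blanket "prepend madda to
alef-initial words" rule, which would corrupt ordinary words such as
`اتاق`. The stemmer is deliberately light: it strips the longest listed
suffix at most twice and never empties a token; a heavier external
stemmer can be plugged in through `NormalizeConfig.stemmer`. The spell
checker is off by default and conservative — it replaces a token only
when exactly one vocabulary word lies at edit distance 1 — because an
aggressive corrector can silently flip sentiment terms. All text is
handled as NFC Unicode; the half-space is U+200C and never splits a
token.

Every text-level operation is idempotent (`O(O(x)) = O(x)`), token and
sentence order are never permuted, and character/spacing/spelling
normalization never changes the number of single-word tokens (merges come
only from affix and compound rules). These invariants are enforced by
property tests.

## Sentiment scoring

Term strengths are integers in {−5..−1} ∪ {+1..+5}; zero is forbidden so
that absence from the lexicon is the only neutral state. Sentence
polarity is the max-positive / min-negative strength with the larger
absolute value; an exact tie yields 0 — neutrality is the only symmetric
resolution since nothing in the strategy prefers either sign.

**Negation** inverts the sign of the shifted token's strength, the
standard shifter semantics for lexicon methods, with scope limited to the
single shifted token (the rule is per-particle, not window-based). A
token is only treated as negated when the stripped remainder is a known
word (lexicon or supplied vocabulary), so person names like `نادر` are
never shifted, and a protected-word list exempts lexical items that begin
with a particle (`نگران`, `ناراحت`, `ناامید`, `نامناسب`, `ناهار`).

**Document score** is the mean of nonzero sentence polarities divided
by 5, i.e. neutral sentences are uninformative rather than diluting.
This maps sentence-level integers onto the reporting scale [−1, +1] (one
all-`−5` document is exactly −1). Review aggregation is the weighted
average V(P) = Σu·Polarity/Σu; usefulness weights default to 1 because no
usefulness signal exists for hospital feedback forms — the interface
accepts arbitrary non-negative weights. Both aggregation levels
(sentences within a review, reviews within a group) are exposed. The
evidence-theoretic sentence combination sometimes used with this scoring
strategy is intentionally **not** implemented; the max-absolute rule plus
weighted averaging is the entire scoring surface.

## Topic modeling

LDA is implemented from scratch as a collapsed Gibbs sampler (the
numba-jitted inner loop makes desk-scale corpora take seconds) so the
computation is fully owned and bit-reproducible for a fixed seed.
Defaults: α = 50/k, β = 0.01, 1000 sweeps with 500 burn-in. φ and θ are
point-estimated by averaging the smoothed count ratios over every
post-burn-in sweep, which keeps rows normalized and strictly positive.
The per-sweep joint log-likelihood (lgamma form, constants dropped) is
recorded as a convergence trace; tests check its 50-sweep block means
rise.

Choosing k: each candidate is fit with the same seed and scored by mean
UMass coherence over its top-10 words, Σ log[(D(wᵢ,wⱼ)+1)/D(wⱼ)]; the
argmax wins and exact ties resolve to the smaller k. Coherence is a
computable proxy for the manual "do the topics read well" review; the
full per-k table is returned so a human can overrule it. Topic labels are
a human judgement and out of scope — the model emits top words only.

## Evaluation protocol

Ratings 3–5 → positive, 1–2 → negative. The 90:10 split is retained even
though the lexicon scorer has no trainable weights — the held-out
fraction is what the reported metrics are computed on, and the training
portion is where a neutral band or lexicon extension would be tuned.
Splits are seeded and label-stratified with largest-remainder
apportionment. Documents scored exactly neutral are dropped from binary
metrics by default (configurable), since the confusion matrix is strictly
two-class. Any metric with a zero denominator is an explicit `None`
marker, never an exception and never a silent 0. AUC is the rank-based
Mann–Whitney statistic on the continuous document score, ties counted ½.

## Synthetic data

The generator emulates the study conditions the toolkit targets: short
feedback comments averaging 41.3 words and 3.9 sentences, three feedback
sections, 1–5 ratings skewed toward satisfaction (8%/12%/15%/30%/35%),
ages drawn in three bins (8.9% under 30, 63.6% 30–60, 27.5% over 60),
a planted topic structure over a real 110-word Persian content
vocabulary, and sentiment terms injected with rating-conditional
strength: every injected sentence in a rating-r comment carries one term
of polarity p(r) drawn from {4,5}, {2,3}, {1}, {−1,−2}, {−3,−4,−5} for
r = 5..1, so the document score p/5 lands in disjoint bands and the
binary label is recoverable by construction. Sentence and per-sentence
word counts are Poisson with floors of 1 and 2.

Negation is sampled **per comment** (probability `negation_rate`): a
"negating author" writes every injected term as a shifter-attached form
of an opposite-sign base (`نبد` for intended +3 when `بد` is −3), which
mirrors how negation use clusters by writer and makes the ablation
meaningful — with detection disabled such comments become entirely
neutral and are misclassified, so accuracy drops by roughly the negation
rate. `out_of_lexicon_rate` replaces an injected term with a pseudo-word,
emulating lexicon coverage gaps.

Surface corruption applies the modeled noise classes — Arabic character
forms, dropped madda, extra spaces/tabs, detached suffixes, split
prefixes, kashida elongation, spelling variants — each at its configured
rate, with **at most one class per token** so that the round trip
`normalize(corrupt(x)) = normalize(x)` holds exactly. That guarantee is
restricted to the modeled classes: real text contains noise combinations
(e.g. elongation inside a madda-dropped word) the normalizer does not
promise to repair.

What passing tests show: the pipeline's stages are correct relative to
their contracts and recover planted structure under the modeled noise.
What they do not show: performance on real Persian prose, whose
vocabulary coverage, irony, and compounded noise are outside the
generator; all accuracy figures are lexicon-relative.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale corpora chosen to make the
statistics stable: 500 documents for label-recovery and topic-recovery
experiments (≈50 words/document for LDA, matched-topic recovery scored by
optimal cosine assignment), 300–400 documents for ablations, 1,000 random
cases for oracle-equivalence checks, and 150–400 Gibbs sweeps where the
defaults would add nothing. Probability rows are validated to 1e−9;
equal-weight aggregation agrees with the arithmetic mean to 1e−12;
sampling seeds are threaded through every stochastic component
(NumPy `default_rng`; the sampler seed is reduced mod 2³¹−1).

## Known limitations

- Lexicon-dependent by design: no learning of term strengths, no
  boosters/emoticons, no irony or sarcasm handling.
- The light stemmer under- and over-stems rare forms (`دکتر` → `دک` with
  the default suffix list); guarantees are consistency, not morphology.
- Negation scope is a single token; clause-level negation is untouched.
- Coherence-based k selection is a proxy; it is reliable on
  well-separated planted topics but can prefer merged topics on diffuse
  real corpora.
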