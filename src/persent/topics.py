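"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Documents are bags of stems; topic assignments are resampled token by
token from the standard collapsed conditional

    p(z_i = t | z_-i, w) ∝ (n_dt + alpha) * (n_tw + beta) / (n_t + V*beta),

and the topic-word (phi) and document-topic (theta) distributions are
point-estimated by averaging the smoothed count ratios over the
post-burn-in sweeps. Runs are bit-reproducible for a fixed seed.

Topic-count selection uses UMass coherence of the top words, mirroring
the manual "do the topics read well" check with a computable proxy:
higher (closer to zero) coherence means the top words of a topic tend to
co-occur in the same documents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegenerateVocabularyError, EmptyCorpusError
from .normalization import NormalizedDocument

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class TopicModelParams:
    k: int
    alpha: float | None = None  # default 50/k
    beta: float = 0.01
    n_iter: int = 1000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.n_iter < 1 or not 0 <= self.burn_in < self.n_iter:
            raise ConfigError("need 0 <= burn_in < n_iter")
        if (self.alpha is not None and self.alpha <= 0) or self.beta <= 0:
            raise ConfigError("concentrations must be positive")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.k


@dataclass(frozen=True)
class TopicModelResult:
    phi: np.ndarray  # k x V
    theta: np.ndarray  # D x k
    assignments: tuple[np.ndarray, ...]  # per-document token topic ids
    log_likelihood_trace: np.ndarray
    vocabulary: tuple[str, ...]
    doc_ids: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.phi.shape[0]


@njit(cache=True)
def _gibbs(tokens, doc_of, doc_len, k, V, D, alpha, beta, n_iter, burn_in, seed):
    np.random.seed(seed)
    N = tokens.shape[0]
    z = np.empty(N, np.int32)
    ndt = np.zeros((D, k), np.int32)
    ntw = np.zeros((k, V), np.int32)
    nt = np.zeros(k, np.int64)
    for i in range(N):
        t = np.random.randint(0, k)
        z[i] = t
        ndt[doc_of[i], t] += 1
        ntw[t, tokens[i]] += 1
        nt[t] += 1
    phi_acc = np.zeros((k, V))
    theta_acc = np.zeros((D, k))
    ll = np.empty(n_iter)
    p = np.empty(k)
    vbeta = V * beta
    for sweep in range(n_iter):
        for i in range(N):
            w = tokens[i]
            d = doc_of[i]
            t = z[i]
            ndt[d, t] -= 1
            ntw[t, w] -= 1
            nt[t] -= 1
            tot = 0.0
            for j in range(k):
                tot += (ndt[d, j] + alpha) * (ntw[j, w] + beta) / (nt[j] + vbeta)
                p[j] = tot
            u = np.random.random() * tot
            tnew = 0
            while p[tnew] < u and tnew < k - 1:
                tnew += 1
            z[i] = tnew
            ndt[d, tnew] += 1
            ntw[tnew, w] += 1
            nt[tnew] += 1
        # joint log-likelihood (constants dropped)
        s = 0.0
        for j in range(k):
            for w in range(V):
                s += math.lgamma(ntw[j, w] + beta)
            s -= math.lgamma(nt[j] + vbeta)
        for d in range(D):
            for j in range(k):
                s += math.lgamma(ndt[d, j] + alpha)
            s -= math.lgamma(doc_len[d] + k * alpha)
        ll[sweep] = s
        if sweep >= burn_in:
            for j in range(k):
                denom = nt[j] + vbeta
                for w in range(V):
                    phi_acc[j, w] += (ntw[j, w] + beta) / denom
            for d in range(D):
                denom_d = doc_len[d] + k * alpha
                for j in range(k):
                    theta_acc[d, j] += (ndt[d, j] + alpha) / denom_d
    nsamp = n_iter - burn_in
    return z, phi_acc / nsamp, theta_acc / nsamp, ll


def _as_stem_lists(corpus) -> list[list[str]]:
    docs = []
    for doc in corpus:
        if isinstance(doc, NormalizedDocument):
            docs.append(doc.stems())
        else:
            docs.append(list(doc))
    return docs


def _doc_id(doc, i) -> str:
    return doc.comment_id if isinstance(doc, NormalizedDocument) else str(i)


def fit_lda(corpus: Sequence, params: TopicModelParams) -> TopicModelResult:
    """Fit LDA on a corpus of NormalizedDocuments (or plain token lists)."""
    if len(corpus) == 0:
        raise EmptyCorpusError("empty corpus")
    docs = _as_stem_lists(corpus)
    if any(len(d) == 0 for d in docs):
        raise EmptyCorpusError("every document needs at least one token")
    vocab = sorted({w for d in docs for w in d})
    if not vocab:
        raise DegenerateVocabularyError("vocabulary is empty")
    index = {w: i for i, w in enumerate(vocab)}
    tokens = np.array([index[w] for d in docs for w in d], dtype=np.int32)
    doc_of = np.array(
        [i for i, d in enumerate(docs) for _ in d], dtype=np.int32
    )
    doc_len = np.array([len(d) for d in docs], dtype=np.int64)
    z, phi, theta, ll = _gibbs(
        tokens,
        doc_of,
        doc_len,
        params.k,
        len(vocab),
        len(docs),
        float(params.effective_alpha),
        float(params.beta),
        params.n_iter,
        params.burn_in,
        int(params.seed) % (2**31 - 1),
    )
    bounds = np.cumsum(doc_len)[:-1]
    assignments = tuple(np.split(np.asarray(z), bounds))
    return TopicModelResult(
        phi=np.asarray(phi),
        theta=np.asarray(theta),
        assignments=assignments,
        log_likelihood_trace=np.asarray(ll),
        vocabulary=tuple(vocab),
        doc_ids=tuple(_doc_id(doc, i) for i, doc in enumerate(corpus)),
    )


def top_words(result: TopicModelResult, topic: int, n: int) -> list[str]:
    """The n highest-probability terms of a topic; ties break lexicographically."""
    if not 0 <= topic < result.k:
        raise IndexError(f"topic {topic} outside 0..{result.k - 1}")
    row = result.phi[topic]
    order = sorted(range(len(row)), key=lambda i: (-row[i], result.vocabulary[i]))
    return [result.vocabulary[i] for i in order[: max(n, 0)]]


def dominant_topic(result: TopicModelResult, doc: int) -> int:
    """Argmax of the document's topic distribution; ties -> lowest index."""
    if not 0 <= doc < result.theta.shape[0]:
        raise IndexError(f"document {doc} outside corpus")
    return int(np.argmax(result.theta[doc]))


def coherence(result: TopicModelResult, corpus: Sequence, top_n: int = 10) -> list[float]:
    """UMass coherence per topic over its top_n words (higher is better)."""
    docs = [set(d) for d in _as_stem_lists(corpus)]
    scores = []
    for t in range(result.k):
        words = top_words(result, t, top_n)
        doc_freq = {w: sum(w in d for d in docs) for w in words}
        c = 0.0
        for i in range(1, len(words)):
            for j in range(i):
                wi, wj = words[i], words[j]
                if doc_freq[wj] == 0:
                    continue
                co = sum(wi in d and wj in d for d in docs)
                c += math.log((co + 1) / doc_freq[wj])
        scores.append(c)
    return scores


def select_k(
    corpus: Sequence,
    k_values: Sequence[int],
    params: TopicModelParams,
    top_n: int = 10,
) -> tuple[int, dict[int, float]]:
    """Fit each candidate k with the same seed and pick the argmax of mean
    UMass coherence; exact ties resolve to the smaller k. Returns the chosen
    k together with the full per-k table for manual review."""
    if not k_values:
        raise ConfigError("k_values must be non-empty")
    table: dict[int, float] = {}
    for k in sorted(k_values):
        result = fit_lda(corpus, replace(params, k=k, alpha=None if params.alpha is None else params.alpha))
        table[k] = float(np.mean(coherence(result, corpus, top_n)))
    best = max(table, key=lambda k: (table[k], -k))
    return best, table
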