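"""LDA topic modelling of patent abstracts via collapsed Gibbs sampling.

Each abstract is treated as a bag of tokens drawn from a mixture of K latent
topics; each topic is a distribution over the vocabulary (symmetric Dirichlet
priors: document-topic concentration ``alpha``, topic-word concentration
``eta``). Inference is collapsed Gibbs sampling over per-token topic
assignments; the sweep kernel is JIT-compiled with numba when available and
falls back to the identical pure-Python loop otherwise, so results do not
depend on the JIT.

Topic quality is scored corpus-internally: UMass semantic coherence (top
terms of a good topic co-occur in documents) and exclusivity (top terms of a
good topic carry little probability under other topics). Topic-number
selection balances the two by min-max normalizing each across the candidate
grid and maximizing their unweighted mean.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from patenttrends.records import PatentRecord

__all__ = [
    "TokenizedCorpus",
    "LDAConfig",
    "TopicModelResult",
    "DEFAULT_STOPLIST",
    "preprocess",
    "fit_lda",
    "coherence",
    "exclusivity",
    "select_topic_number",
    "top_terms",
    "generic_terms",
]

#: Minimal English function-word stoplist for abstract preprocessing.
DEFAULT_STOPLIST = frozenset(
    """a an and are as at be by for from has have in is it its of on or that the
    this to was were will with which said wherein thereof comprising method
    invention present provided according can may one more each other when where
    into also such between than then there their these those using used use
    being further both same after before during within without least
    """.split()
)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


# ---------------------------------------------------------------------------
# containers


@dataclass
class TokenizedCorpus:
    """Bag-of-words corpus: token-id sequences plus the id->term vocabulary."""

    documents: list[np.ndarray]
    vocabulary: list[str]
    doc_ids: list[str]
    dropped_doc_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.documents) != len(self.doc_ids):
            raise ValueError("doc_ids must align 1:1 with documents")
        if len(set(self.doc_ids)) != len(self.doc_ids):
            raise ValueError("doc_ids must be unique")
        v = len(self.vocabulary)
        for doc in self.documents:
            if len(doc) and int(np.max(doc)) >= v:
                raise ValueError("token id out of vocabulary range")

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.documents))

    def document_frequencies(self) -> np.ndarray:
        """Number of documents containing each term at least once."""
        df = np.zeros(self.vocab_size, dtype=np.int64)
        for doc in self.documents:
            df[np.unique(doc)] += 1
        return df


@dataclass
class LDAConfig:
    """Collapsed-Gibbs settings; ``alpha`` defaults to the 50/K heuristic."""

    n_topics: int
    alpha: float | None = None
    eta: float = 0.01
    gibbs_iterations: int = 1000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError("need at least 2 topics")
        if self.alpha is None:
            self.alpha = 50.0 / self.n_topics
        if self.alpha <= 0 or self.eta <= 0:
            raise ValueError("concentrations must be positive")
        if not 0 <= self.burn_in < self.gibbs_iterations:
            raise ValueError("burn_in must be < gibbs_iterations")


@dataclass
class TopicModelResult:
    """Fitted LDA state.

    ``topic_word`` is (K, V) with rows summing to 1; ``doc_topic`` is (D, K)
    with rows summing to 1. ``assignments`` holds the final token-topic
    labels aligned with ``token_doc``/``token_word``. ``token_count_trace``
    records the total assigned-token count after every sweep (a conservation
    audit), ``log_likelihood_trace`` the collapsed joint log p(w, z).
    """

    topic_word: np.ndarray
    doc_topic: np.ndarray
    assignments: np.ndarray
    token_doc: np.ndarray
    token_word: np.ndarray
    vocabulary: list[str]
    doc_ids: list[str]
    log_likelihood_trace: np.ndarray
    token_count_trace: np.ndarray
    config: LDAConfig
    coherence: np.ndarray | None = None
    exclusivity: np.ndarray | None = None

    @property
    def n_topics(self) -> int:
        return self.topic_word.shape[0]


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    records: Sequence[PatentRecord],
    stoplist: Sequence[str] | frozenset = DEFAULT_STOPLIST,
    min_term_count: int = 2,
    lowercase: bool = True,
) -> TokenizedCorpus:
    """Tokenize abstracts into a :class:`TokenizedCorpus`.

    Tokenization is on unicode word boundaries; stopwords and terms occurring
    fewer than ``min_term_count`` times corpus-wide are removed. Documents
    emptied by filtering are dropped and reported via ``dropped_doc_ids``;
    if every document empties out, that is an error, not an empty corpus.
    """
    stop = {s.lower() for s in stoplist}
    raw_docs: list[list[str]] = []
    ids: list[str] = []
    for rec in records:
        text = rec.abstract.lower() if lowercase else rec.abstract
        toks = [t for t in _TOKEN_RE.findall(text) if t not in stop]
        raw_docs.append(toks)
        ids.append(rec.record_id)

    counts: dict[str, int] = {}
    for toks in raw_docs:
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_term_count)
    index = {t: i for i, t in enumerate(vocab)}

    documents: list[np.ndarray] = []
    kept_ids: list[str] = []
    dropped: list[str] = []
    for rid, toks in zip(ids, raw_docs):
        enc = np.array([index[t] for t in toks if t in index], dtype=np.int32)
        if len(enc):
            documents.append(enc)
            kept_ids.append(rid)
        else:
            dropped.append(rid)
    if not documents:
        raise ValueError("all documents are empty after preprocessing")
    return TokenizedCorpus(documents, vocab, kept_ids, dropped)


def generic_terms(corpus: TokenizedCorpus, df_threshold: float = 0.5) -> set[str]:
    """Terms appearing in more than ``df_threshold`` of documents (too generic
    to characterize a topic)."""
    df = corpus.document_frequencies()
    cut = df_threshold * corpus.n_docs
    return {corpus.vocabulary[i] for i in np.nonzero(df > cut)[0]}


# ---------------------------------------------------------------------------
# collapsed Gibbs sweep (numba-accelerated when available)


def _gibbs_sweep_py(doc_of, word_of, z, n_dk, n_wk, n_k, alpha, eta, u):
    v = n_wk.shape[0]
    k_topics = n_k.shape[0]
    cum = np.empty(k_topics)
    veta = v * eta
    for t in range(z.shape[0]):
        d = doc_of[t]
        w = word_of[t]
        k = z[t]
        n_dk[d, k] -= 1
        n_wk[w, k] -= 1
        n_k[k] -= 1
        total = 0.0
        for kk in range(k_topics):
            total += (n_dk[d, kk] + alpha) * (n_wk[w, kk] + eta) / (n_k[kk] + veta)
            cum[kk] = total
        r = u[t] * total
        knew = 0
        while cum[knew] < r:
            knew += 1
        z[t] = knew
        n_dk[d, knew] += 1
        n_wk[w, knew] += 1
        n_k[knew] += 1


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _gibbs_sweep = njit(cache=False)(_gibbs_sweep_py)
except Exception:  # pragma: no cover
    _gibbs_sweep = _gibbs_sweep_py


def _collapsed_log_likelihood(n_dk, n_wk, n_k, alpha, eta) -> float:
    """Collapsed joint log p(w, z) up to assignment-independent constants."""
    v, k = n_wk.shape
    ll = float(np.sum(gammaln(n_wk + eta))) - float(np.sum(gammaln(n_k + v * eta)))
    n_d = n_dk.sum(axis=1)
    ll += float(np.sum(gammaln(n_dk + alpha))) - float(np.sum(gammaln(n_d + k * alpha)))
    return ll


def fit_lda(corpus: TokenizedCorpus, config: LDAConfig) -> TopicModelResult:
    """Fit LDA by collapsed Gibbs sampling.

    Point estimates of ``topic_word`` and ``doc_topic`` come from the final
    smoothed counts. Identical corpus + config (including seed) reproduce the
    fit exactly. Per-topic coherence (UMass, top 10 terms) and exclusivity
    are attached to the result.
    """
    if corpus.n_docs == 0:
        raise ValueError("corpus is empty")
    k = config.n_topics
    v = corpus.vocab_size
    if k > v:
        raise ValueError(f"n_topics={k} exceeds vocabulary size {v}")

    doc_of = np.concatenate(
        [np.full(len(d), i, dtype=np.int32) for i, d in enumerate(corpus.documents)]
    )
    word_of = np.concatenate(corpus.documents).astype(np.int32)
    n_tok = len(word_of)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    z = rng.integers(0, k, size=n_tok).astype(np.int32)

    n_dk = np.zeros((corpus.n_docs, k), dtype=np.int64)
    n_wk = np.zeros((v, k), dtype=np.int64)
    n_k = np.zeros(k, dtype=np.int64)
    np.add.at(n_dk, (doc_of, z), 1)
    np.add.at(n_wk, (word_of, z), 1)
    np.add.at(n_k, z, 1)

    ll_trace = np.empty(config.gibbs_iterations)
    tok_trace = np.empty(config.gibbs_iterations, dtype=np.int64)
    for it in range(config.gibbs_iterations):
        u = rng.random(n_tok)
        _gibbs_sweep(doc_of, word_of, z, n_dk, n_wk, n_k, config.alpha, config.eta, u)
        tok_trace[it] = int(n_k.sum())
        ll_trace[it] = _collapsed_log_likelihood(n_dk, n_wk, n_k, config.alpha, config.eta)

    topic_word = (n_wk.T + config.eta).astype(float)
    topic_word /= topic_word.sum(axis=1, keepdims=True)
    doc_topic = (n_dk + config.alpha).astype(float)
    doc_topic /= doc_topic.sum(axis=1, keepdims=True)

    result = TopicModelResult(
        topic_word=topic_word,
        doc_topic=doc_topic,
        assignments=z,
        token_doc=doc_of,
        token_word=word_of,
        vocabulary=list(corpus.vocabulary),
        doc_ids=list(corpus.doc_ids),
        log_likelihood_trace=ll_trace,
        token_count_trace=tok_trace,
        config=config,
    )
    result.coherence = coherence(result, corpus)
    result.exclusivity = exclusivity(result)
    return result


# ---------------------------------------------------------------------------
# model scoring


def _top_term_ids(model: TopicModelResult, topic: int, n: int) -> np.ndarray:
    order = np.argsort(-model.topic_word[topic], kind="stable")
    return order[:n]


def coherence(
    model: TopicModelResult, corpus: TokenizedCorpus, top_n: int = 10
) -> np.ndarray:
    """UMass semantic coherence per topic.

    For each topic's ``top_n`` terms ranked by probability, sums
    ``log((codf(v_m, v_l) + 1) / df(v_l))`` over ordered pairs ``m > l``,
    where df is document frequency and codf co-document frequency. A term
    absent from the corpus contributes through the +1 smoothing only (its df
    denominator is floored at 1). Higher is more coherent.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    doc_sets = [set(map(int, np.unique(d))) for d in corpus.documents]
    df = corpus.document_frequencies()
    scores = np.zeros(model.n_topics)
    for topic in range(model.n_topics):
        ids = _top_term_ids(model, topic, top_n)
        score = 0.0
        for m in range(1, len(ids)):
            for l in range(m):
                w_m, w_l = int(ids[m]), int(ids[l])
                co = sum(1 for s in doc_sets if w_m in s and w_l in s)
                score += math.log((co + 1) / max(int(df[w_l]), 1))
        scores[topic] = score
    return scores


def exclusivity(model: TopicModelResult, top_n: int = 10) -> np.ndarray:
    """Exclusivity per topic: mean share of its top terms' probability mass.

    For each top term w of topic k the share is
    ``P(w|k) / sum_k' P(w|k')``; the topic score is the mean over its
    ``top_n`` terms. Lies in (0, 1]; equals 1 iff the top terms have zero
    mass under every other topic.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    col_sums = model.topic_word.sum(axis=0)
    scores = np.zeros(model.n_topics)
    for topic in range(model.n_topics):
        ids = _top_term_ids(model, topic, top_n)
        shares = model.topic_word[topic, ids] / col_sums[ids]
        scores[topic] = float(shares.mean())
    return scores


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-15:
        return np.full_like(x, 0.5, dtype=float)
    return (x - lo) / (hi - lo)


def select_topic_number(
    corpus: TokenizedCorpus,
    k_grid: Sequence[int],
    config_template: LDAConfig | None = None,
    top_n: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose K by balancing mean coherence against mean exclusivity.

    Fits LDA for each K in ``k_grid`` (seeds derived from the template seed),
    min-max normalizes mean coherence and mean exclusivity across the grid,
    and picks the K maximizing their unweighted mean (earliest grid entry on
    ties). Returns the chosen K and the full score table for human review.
    """
    if not len(k_grid):
        raise ValueError("k_grid must be non-empty")
    rows = []
    for k in k_grid:
        if config_template is None:
            cfg = LDAConfig(n_topics=k)
        else:
            cfg = LDAConfig(
                n_topics=k,
                alpha=None,  # rescale with K via the 50/K heuristic
                eta=config_template.eta,
                gibbs_iterations=config_template.gibbs_iterations,
                burn_in=config_template.burn_in,
                seed=(config_template.seed * 131 + k) % (2**31),
            )
        model = fit_lda(corpus, cfg)
        eff_top_n = min(top_n, corpus.vocab_size)
        rows.append(
            {
                "k": k,
                "coherence": float(np.mean(coherence(model, corpus, max(eff_top_n, 2)))),
                "exclusivity": float(np.mean(exclusivity(model, eff_top_n))),
            }
        )
    table = pd.DataFrame(rows)
    table["coherence_norm"] = _minmax(table["coherence"].to_numpy())
    table["exclusivity_norm"] = _minmax(table["exclusivity"].to_numpy())
    table["score"] = 0.5 * (table["coherence_norm"] + table["exclusivity_norm"])
    k_star = int(table.loc[table["score"].idxmax(), "k"])
    return k_star, table


def top_terms(
    model: TopicModelResult,
    topic: int,
    n: int = 5,
    generic_stoplist: Sequence[str] | set = (),
) -> tuple[list[str], bool]:
    """First ``n`` non-generic terms of a topic, ranked by P(term | topic).

    Stoplisted (generic) terms are skipped. Returns ``(terms, truncated)``
    where ``truncated`` flags that fewer than ``n`` non-generic terms exist.
    """
    if not 0 <= topic < model.n_topics:
        raise ValueError(f"topic {topic} out of range")
    stop = {s.lower() for s in generic_stoplist}
    order = np.argsort(-model.topic_word[topic], kind="stable")
    terms = []
    for idx in order:
        term = model.vocabulary[int(idx)]
        if term.lower() in stop:
            continue
        terms.append(term)
        if len(terms) == n:
            return terms, False
    return terms, True
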