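import datetime as dt

import numpy as np
import pytest

from patenttrends import (
    MonthlyCountSeries,
    PatentRecord,
    SimCorpusConfig,
    SimSeriesConfig,
    simulate_patent_corpus,
)


def make_series(counts, start="1970-01", taxon="bear"):
    return MonthlyCountSeries(taxon, start, np.asarray(counts))


def make_record(rid, abstract="", title="", date="1990-06-15", taxon="bear", **kw):
    return PatentRecord(
        record_id=rid,
        title=title,
        abstract=abstract,
        priority_date=dt.date.fromisoformat(date),
        jurisdiction="CN",
        taxon=taxon,
        **kw,
    )


def disjoint_topic_rows(n_topics, block, decay=None):
    """Planted topic-word rows with disjoint supports of ``block`` terms each.

    ``decay`` < 1 gives a geometric (Zipf-like) profile within each block;
    None gives uniform blocks.
    """
    v = n_topics * block
    tw = np.zeros((n_topics, v))
    w = np.ones(block) if decay is None else decay ** np.arange(block)
    w = w / w.sum()
    for k in range(n_topics):
        tw[k, k * block : (k + 1) * block] = w
    return tw


def planted_corpus(
    n_topics=2,
    block=50,
    decay=None,
    monthly_mean=250.0,
    n_months=2,
    doc_length_mean=50.0,
    seed=0,
    decoy_fraction=0.0,
    taxon="bear",
):
    """Corpus with disjoint-support planted topics driving ~monthly_mean docs/month."""
    tw = disjoint_topic_rows(n_topics, block, decay)
    series = {
        taxon: SimSeriesConfig(
            n_months=n_months,
            mu_early=monthly_mean,
            mu_late=monthly_mean,
            phi_early=1000.0,  # near-Poisson: keep the doc count close to its mean
            phi_late=1000.0,
            seed=seed,
        )
    }
    cfg = SimCorpusConfig(
        series=series,
        n_topics_true=n_topics,
        vocabulary_size=tw.shape[1],
        topic_word=tw,
        doc_length_mean=doc_length_mean,
        doc_topic_concentration=0.3,
        decoy_fraction=decoy_fraction,
        seed=seed,
    )
    return simulate_patent_corpus(cfg)


def best_match_tv(fitted_topic_word, fitted_vocab, truth):
    """Min-over-permutations max per-topic total-variation distance to truth.

    Fitted rows are projected onto the planted vocabulary and renormalized
    (the corpus may contain extra tokens, e.g. taxon keywords).
    """
    from itertools import permutations

    k = truth.topic_word.shape[0]
    vi = {t: i for i, t in enumerate(fitted_vocab)}
    proj = np.zeros((fitted_topic_word.shape[0], len(truth.vocabulary)))
    for j, term in enumerate(truth.vocabulary):
        if term in vi:
            proj[:, j] = fitted_topic_word[:, vi[term]]
    proj = proj / proj.sum(axis=1, keepdims=True)
    best = np.inf
    for perm in permutations(range(proj.shape[0]), k):
        tv = max(
            0.5 * np.abs(proj[perm[t]] - truth.topic_word[t]).sum() for t in range(k)
        )
        best = min(best, tv)
    return best


@pytest.fixture
def bear_records():
    return [
        make_record("B1", abstract="bear bile powder for medicine", date="1990-01-15"),
        make_record("B2", abstract="bear gall beverage production", date="1990-01-20"),
        make_record("B3", abstract="synthetic bear bile analogue", date="1990-02-01"),
    ]
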