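"""LDA: preprocessing, collapsed Gibbs, coherence/exclusivity, K selection."""

import math

import numpy as np
import pytest

from patenttrends import (
    LDAConfig,
    TokenizedCorpus,
    fit_lda,
    preprocess,
    select_topic_number,
    top_terms,
)
from patenttrends.topics import TopicModelResult, coherence, exclusivity, generic_terms

from conftest import best_match_tv, make_record, planted_corpus


class TestPreprocess:
    def test_tokenizes_on_word_boundaries(self):
        recs = [make_record("T1", abstract="Bear bile powder")]
        corpus = preprocess(recs, stoplist=(), min_term_count=1)
        assert sorted(corpus.vocabulary) == ["bear", "bile", "powder"]
        assert len(corpus.documents[0]) == 3

    def test_stoplist_removes_terms(self):
        recs = [make_record("T1", abstract="Bear bile powder")]
        corpus = preprocess(recs, stoplist=["bear"], min_term_count=1)
        assert sorted(corpus.vocabulary) == ["bile", "powder"]

    def test_min_term_count_prunes_rare_terms(self):
        recs = [
            make_record("T1", abstract="bile bile powder"),
            make_record("T2", abstract="bile extract extract"),
        ]
        corpus = preprocess(recs, stoplist=(), min_term_count=2)
        assert "powder" not in corpus.vocabulary
        assert {"bile", "extract"} <= set(corpus.vocabulary)

    def test_emptied_documents_dropped_with_report(self):
        recs = [
            make_record("T1", abstract="bile bile"),
            make_record("T2", abstract="the and of"),
        ]
        corpus = preprocess(recs, min_term_count=1)
        assert corpus.doc_ids == ["T1"]
        assert corpus.dropped_doc_ids == ["T2"]

    def test_all_empty_is_an_error(self):
        recs = [make_record("T1", abstract="the and")]
        with pytest.raises(ValueError):
            preprocess(recs, min_term_count=1)


def tiny_model(topic_word, vocab=None):
    """Hand-built TopicModelResult for scoring-function tests."""
    tw = np.asarray(topic_word, dtype=float)
    k, v = tw.shape
    vocab = vocab or [f"w{i}" for i in range(v)]
    return TopicModelResult(
        topic_word=tw,
        doc_topic=np.full((1, k), 1 / k),
        assignments=np.zeros(1, dtype=np.int32),
        token_doc=np.zeros(1, dtype=np.int32),
        token_word=np.zeros(1, dtype=np.int32),
        vocabulary=list(vocab),
        doc_ids=["d0"],
        log_likelihood_trace=np.zeros(1),
        token_count_trace=np.ones(1, dtype=np.int64),
        config=LDAConfig(n_topics=max(k, 2)),
    )


class TestFitLda:
    def test_normalization_and_full_assignment(self):
        recs = [make_record(f"D{i}", abstract="bile powder") for i in range(4)]
        corpus = preprocess(recs, min_term_count=1)
        model = fit_lda(corpus, LDAConfig(n_topics=2, gibbs_iterations=20,
                                          burn_in=10, seed=0))
        assert np.allclose(model.topic_word.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.doc_topic.sum(axis=1), 1.0, atol=1e-9)
        assert len(model.assignments) == corpus.n_tokens

    def test_token_count_conserved_at_every_sweep(self):
        records, _ = planted_corpus(seed=0, monthly_mean=30, doc_length_mean=20)
        corpus = preprocess(records, min_term_count=1)
        model = fit_lda(corpus, LDAConfig(n_topics=3, gibbs_iterations=50,
                                          burn_in=10, seed=1))
        assert (model.token_count_trace == corpus.n_tokens).all()

    def test_seeded_reproducibility(self):
        records, _ = planted_corpus(seed=3, monthly_mean=30)
        corpus = preprocess(records, min_term_count=1)
        cfg = LDAConfig(n_topics=2, gibbs_iterations=30, burn_in=10, seed=7)
        a = fit_lda(corpus, cfg)
        b = fit_lda(corpus, cfg)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.array_equal(a.topic_word, b.topic_word)

    def test_recovers_disjoint_planted_topics(self):
        records, truth = planted_corpus(n_topics=2, block=50, seed=0,
                                        monthly_mean=250, doc_length_mean=50)
        corpus = preprocess(records, min_term_count=1)
        model = fit_lda(corpus, LDAConfig(n_topics=2, gibbs_iterations=200,
                                          burn_in=100, seed=1))
        assert best_match_tv(model.topic_word, model.vocabulary, truth) < 0.1

    def test_k_larger_than_vocabulary_rejected(self):
        recs = [make_record("D1", abstract="bile bile powder powder")]
        corpus = preprocess(recs, min_term_count=1)
        with pytest.raises(ValueError):
            fit_lda(corpus, LDAConfig(n_topics=5, gibbs_iterations=10, burn_in=0))


class TestCoherence:
    def test_co_occurring_top_terms_score_higher(self):
        # same marginal frequencies; topic A's terms co-occur, topic B's never do
        docs = [
            np.array([0, 1]), np.array([0, 1]),  # a,b together
            np.array([2]), np.array([3]),        # c,d apart
            np.array([2]), np.array([3]),
        ]
        corpus = TokenizedCorpus(docs, ["a", "b", "c", "d"],
                                 [f"d{i}" for i in range(6)])
        model = tiny_model([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]])
        scores = coherence(model, corpus, top_n=2)
        assert scores[0] > scores[1]

    def test_hand_counted_two_document_example(self):
        # df(a)=2, df(b)=1, codf(a,b)=1; top order a then b
        docs = [np.array([0, 1]), np.array([0])]
        corpus = TokenizedCorpus(docs, ["a", "b"], ["d0", "d1"])
        model = tiny_model([[0.7, 0.3]])
        expected = math.log((1 + 1) / 2)
        assert coherence(model, corpus, top_n=2)[0] == pytest.approx(expected, abs=1e-12)

    def test_closed_form_when_both_terms_in_all_documents(self):
        d_total = 5
        docs = [np.array([0, 1]) for _ in range(d_total)]
        corpus = TokenizedCorpus(docs, ["a", "b"], [f"d{i}" for i in range(d_total)])
        model = tiny_model([[0.6, 0.4]])
        expected = math.log((d_total + 1) / d_total)
        assert coherence(model, corpus, top_n=2)[0] == pytest.approx(expected, abs=1e-12)

    def test_absent_term_smoothing_never_divides_by_zero(self):
        docs = [np.array([0])]
        corpus = TokenizedCorpus(docs, ["a"], ["d0"])
        # model vocabulary has an extra term never seen in the corpus
        model = tiny_model([[0.5, 0.5]], vocab=["b_unseen", "a"])
        score = coherence(model, corpus, top_n=2)
        assert np.isfinite(score).all()


class TestExclusivity:
    def test_disjoint_supports_score_one(self):
        model = tiny_model([[0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]])
        assert np.allclose(exclusivity(model, top_n=2), 1.0)

    def test_identical_topics_score_half(self):
        model = tiny_model([[0.6, 0.4], [0.6, 0.4]])
        assert np.allclose(exclusivity(model, top_n=2), 0.5)

    def test_hand_built_three_word_example(self):
        tw = np.array([[0.6, 0.3, 0.1], [0.2, 0.2, 0.6]])
        model = tiny_model(tw)
        # topic 0 top-2: w0 (share 0.6/0.8), w1 (share 0.3/0.5)
        expected0 = (0.6 / 0.8 + 0.3 / 0.5) / 2
        assert exclusivity(model, top_n=2)[0] == pytest.approx(expected0, abs=1e-12)


class TestSelection:
    def test_singleton_grid_returns_that_k(self):
        records, _ = planted_corpus(seed=1, monthly_mean=30)
        corpus = preprocess(records, min_term_count=1)
        cfg = LDAConfig(n_topics=2, gibbs_iterations=30, burn_in=10, seed=0)
        k, table = select_topic_number(corpus, [4], cfg)
        assert k == 4 and len(table) == 1

    def test_score_table_has_raw_and_normalized_columns(self):
        records, _ = planted_corpus(seed=1, monthly_mean=30)
        corpus = preprocess(records, min_term_count=1)
        cfg = LDAConfig(n_topics=2, gibbs_iterations=30, burn_in=10, seed=0)
        _, table = select_topic_number(corpus, [2, 3], cfg)
        assert list(table["k"]) == [2, 3]
        for col in ("coherence", "exclusivity", "coherence_norm",
                    "exclusivity_norm", "score"):
            assert col in table.columns

    def test_planted_three_topic_corpus_selects_three(self):
        # Zipf-profile disjoint topics; single representative run (the
        # multi-seed selection experiment lives in the acceptance suite)
        records, _ = planted_corpus(n_topics=3, block=40, decay=0.85,
                                    monthly_mean=150, doc_length_mean=40, seed=0)
        corpus = preprocess(records, min_term_count=1)
        cfg = LDAConfig(n_topics=2, gibbs_iterations=200, burn_in=100, seed=0)
        k, _ = select_topic_number(corpus, [2, 3, 6], cfg)
        assert k == 3


class TestTopTerms:
    model = tiny_model([[0.4, 0.3, 0.15, 0.1, 0.05]],
                       vocab=["alpha", "beta", "gamma", "delta", "eps"])

    def test_plain_ranking(self):
        terms, truncated = top_terms(self.model, 0, n=3)
        assert terms == ["alpha", "beta", "gamma"] and not truncated

    def test_stoplisted_rank_one_term_skipped(self):
        terms, _ = top_terms(self.model, 0, n=3, generic_stoplist=["alpha"])
        assert terms == ["beta", "gamma", "delta"]

    def test_n_beyond_vocabulary_sets_warning(self):
        terms, truncated = top_terms(self.model, 0, n=10)
        assert len(terms) == 5 and truncated

    def test_generic_terms_by_document_frequency(self):
        docs = [np.array([0, 1]), np.array([0, 2]), np.array([0, 1])]
        corpus = TokenizedCorpus(docs, ["common", "mid", "rare"], ["a", "b", "c"])
        assert generic_terms(corpus, 0.5) == {"common", "mid"}
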