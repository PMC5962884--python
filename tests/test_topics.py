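"""Abstract preprocessing and topic-model fitting / recovery."""

import numpy as np
import pytest
import scipy.optimize

from fundingaudit.records import CorpusError
from fundingaudit.stemming import porter_stem
from fundingaudit.synth import generate_topic_corpus
from fundingaudit.topics import (TopicModel, dominant_topic_assignment,
                                 fit_topic_model, preprocess_texts,
                                 topic_summary)

from conftest import make_record


def _align_to_truth(model, truth):
    """Best bipartite assignment of fitted topics onto planted topics by
    word-distribution cosine; returns (cosines, fitted phi/theta reordered)."""
    vidx = [truth["vocab"].index(w) for w in model.vocabulary]
    phi_f = np.zeros_like(truth["phi"])
    phi_f[:, vidx] = model.word_topic
    phi_t = truth["phi"]
    sim = (phi_t @ phi_f.T
           / (np.linalg.norm(phi_t, axis=1)[:, None]
              * np.linalg.norm(phi_f, axis=1)[None, :]))
    rows, cols = scipy.optimize.linear_sum_assignment(-sim)
    return sim[rows, cols], phi_f[cols], model.doc_topic[:, cols]


class TestPreprocess:
    def test_porter_stemming_examples(self):
        assert [porter_stem(w) for w in ["energy", "balance", "exercise"]] \
            == ["energi", "balanc", "exercis"]

    def test_stopword_only_document_dropped(self):
        tokens, vocab, kept = preprocess_texts(
            ["Energy balance and exercise.", "and the of to"])
        assert kept == [0]
        assert tokens == [["energi", "balanc", "exercis"]]

    def test_all_empty_fatal(self):
        with pytest.raises(CorpusError):
            preprocess_texts(["the and of", "to a"])

    def test_numbers_and_punctuation_stripped(self):
        tokens, _, _ = preprocess_texts(["12 mg/dL glucose, p<0.05!"])
        assert tokens == [["mg", "dl", "glucos"]]

    def test_fixture_corpus_vocabulary_matches_generator(self):
        docs, truth = generate_topic_corpus(50, 2, 80, 40, 0.2, seed=1)
        _, vocab, kept = preprocess_texts(docs)
        assert sorted(vocab) == sorted(truth["vocab"])
        assert len(kept) == 50


class TestFit:
    def test_seeded_determinism(self):
        docs, _ = generate_topic_corpus(60, 2, 40, 30, 0.2, seed=2)
        tokens, vocab, _ = preprocess_texts(docs)
        m1 = fit_topic_model(tokens, 2, n_iter=200, burn_in=50, seed=9)
        m2 = fit_topic_model(tokens, 2, n_iter=200, burn_in=50, seed=9)
        assert np.array_equal(m1.doc_topic, m2.doc_topic)
        assert np.array_equal(m1.word_topic, m2.word_topic)

    def test_probability_tables_normalized(self):
        docs, _ = generate_topic_corpus(60, 3, 60, 30, 0.2, seed=3)
        tokens, _, _ = preprocess_texts(docs)
        m = fit_topic_model(tokens, 3, n_iter=200, burn_in=50, seed=3)
        assert np.allclose(m.doc_topic.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(m.word_topic.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_inputs_fatal(self):
        with pytest.raises(CorpusError):
            fit_topic_model([["a", "b"]], k=1)
        with pytest.raises(CorpusError):
            fit_topic_model([["a"], ["a"]], k=2)   # vocabulary smaller than 2

    def test_disjoint_vocabulary_recovery(self):
        """Planted-topic recovery on the separable two-topic corpus."""
        docs, truth = generate_topic_corpus(200, 2, 100, 60, 0.1, seed=3)
        tokens, vocab, _ = preprocess_texts(docs)
        model = fit_topic_model(tokens, 2, seed=3, vocabulary=vocab)
        cosines, _, _ = _align_to_truth(model, truth)
        assert (cosines >= 0.95).all()

    def test_independent_variational_fit_agrees(self):
        """Cross-check: an independent variational-Bayes implementation
        recovers the same planted topics on the separable corpus."""
        from sklearn.decomposition import LatentDirichletAllocation
        from sklearn.feature_extraction.text import CountVectorizer

        docs, truth = generate_topic_corpus(200, 2, 100, 60, 0.1, seed=3)
        vec = CountVectorizer(vocabulary=truth["vocab"])
        X = vec.fit_transform(docs)
        lda = LatentDirichletAllocation(n_components=2, random_state=0,
                                        max_iter=30)
        lda.fit(X)
        phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
        phi_t = truth["phi"]
        sim = (phi_t @ phi.T
               / (np.linalg.norm(phi_t, axis=1)[:, None]
                  * np.linalg.norm(phi, axis=1)[None, :]))
        r, c = scipy.optimize.linear_sum_assignment(-sim)
        assert (sim[r, c] >= 0.95).all()


class TestDominance:
    def _model(self, doc_topic):
        doc_topic = np.asarray(doc_topic, dtype=float)
        k = doc_topic.shape[1]
        return TopicModel(k=k, word_topic=np.full((k, 2), 0.5),
                          doc_topic=doc_topic, vocabulary=["a", "b"],
                          doc_ids=[f"d{i}" for i in range(len(doc_topic))],
                          seed=0, alpha=1 / k, beta=0.01, n_iter=0, burn_in=0)

    def test_ratio_arithmetic(self):
        model = self._model([[0.6, 0.3, 0.1]])
        (topic, ratio), = dominant_topic_assignment(model).values()
        assert topic == 0 and ratio == pytest.approx(2.0)

    def test_uniform_tie_goes_to_lowest_topic(self):
        model = self._model([[1 / 3, 1 / 3, 1 / 3]])
        (topic, ratio), = dominant_topic_assignment(model).values()
        assert topic == 0 and ratio == pytest.approx(1.0)

    def test_summary_shares_and_ratios(self):
        model = self._model([[0.8, 0.2], [0.7, 0.3], [0.1, 0.9]])
        summary = topic_summary(model)
        assert summary.shares_pct[0] + summary.shares_pct[1] == \
            pytest.approx(100.0)
        assert summary.shares_pct[0] == pytest.approx(66.7)
        assert all(r >= 1 for r in summary.mean_ratio.values()
                   if not np.isnan(r))

    def test_single_dominant_topic_share_100(self):
        model = self._model([[0.9, 0.1], [0.8, 0.2]])
        summary = topic_summary(model)
        assert summary.shares_pct[0] == 100.0

    def test_top_words_of_planted_topic(self):
        docs, truth = generate_topic_corpus(200, 2, 40, 60, 0.1, seed=6)
        tokens, vocab, _ = preprocess_texts(docs)
        model = fit_topic_model(tokens, 2, seed=6, vocabulary=vocab)
        cosines, phi_aligned, _ = _align_to_truth(model, truth)
        # the top-7 fitted stems of each topic lie in its planted block
        for t in range(2):
            block = {truth["vocab"][i] for i in np.where(truth["phi"][t] > 0)[0]}
            fitted_topic = int(np.argmax([
                np.dot(truth["phi"][t],
                       np.asarray([model.word_topic[j][model.vocabulary.index(w)]
                                   if w in model.vocabulary else 0.0
                                   for w in truth["vocab"]]))
                for j in range(2)]))
            top7 = {w for w, _ in model.top_words(fitted_topic, 7)}
            assert top7 <= block
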