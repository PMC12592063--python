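"""Dictionary filtering, LDA contracts, overlap/coherence, model selection."""
from __future__ import annotations

import numpy as np
import pytest

from themetrace import topic_model as tm
from themetrace.corpus_io import TokenizedDocument
from themetrace.errors import FilterError

from conftest import make_topic_model


def doc(*tokens, doc_id="d", year=2000):
    return TokenizedDocument(doc_id, tuple(tokens), year)


def docs_from(token_lists):
    return [doc(*toks, doc_id=f"d{i}") for i, toks in enumerate(token_lists)]


class TestBuildDictionary:
    def test_min_doc_count_boundary(self):
        corpus = docs_from([["w", "x"], ["w", "x"], ["x"], ["x"]])
        d = tm.build_dictionary(corpus, min_doc_count=3, max_doc_fraction=1.0)
        assert "w" not in d and "x" in d

    def test_max_fraction_boundary(self):
        corpus = docs_from([["w", "y"], ["w", "y"], ["w", "y"], ["y"]])
        # w in 3 of 4 docs = 75% > 50% -> removed; y in 100% -> removed too
        with pytest.raises(FilterError):
            tm.build_dictionary(corpus, min_doc_count=3, max_doc_fraction=0.5)

    def test_exactly_half_retained(self):
        """A word in exactly 50% of documents survives the <=0.5 filter."""
        corpus = docs_from([["w", "z"]] * 5 + [["z"]] * 5)
        d = tm.build_dictionary(corpus, min_doc_count=3, max_doc_fraction=0.5)
        assert "w" in d and "z" not in d

    def test_ids_sorted_by_word(self):
        corpus = docs_from([["b", "a", "c"]] * 3)
        d = tm.build_dictionary(corpus, min_doc_count=1, max_doc_fraction=1.0)
        assert d.words == ("a", "b", "c")
        assert d.id_for("a") == 0

    def test_empty_vocabulary_reports_thresholds(self):
        corpus = docs_from([["a"], ["b"]])
        with pytest.raises(FilterError, match="min_doc_count=3"):
            tm.build_dictionary(corpus)


class TestBow:
    def test_counts_and_empty_drop(self):
        corpus = docs_from([["a", "a", "b"], ["zzz"]])
        d = tm.build_dictionary(corpus[:1], min_doc_count=1, max_doc_fraction=1.0)
        bows, dropped = tm.to_bow(corpus, d)
        assert bows[0].entries == ((0, 2), (1, 1))  # a=0 twice, b=1 once
        assert dropped == ["d1"]
        assert bows[0].n_tokens == 3


class TestTrainLda:
    def _tiny(self, K=3, reps=20, docs_per_word=4):
        words = [f"w{i}" for i in range(K)]
        corpus = []
        for w in words:
            for j in range(docs_per_word):
                corpus.append(doc(*[w] * reps, doc_id=f"{w}_{j}"))
        d = tm.build_dictionary(corpus, min_doc_count=1, max_doc_fraction=1.0)
        bow, _ = tm.to_bow(corpus, d)
        return corpus, d, bow

    def test_row_normalization_contract(self):
        _, d, bow = self._tiny()
        m = tm.train_lda(bow, d, K=3, seed=0, passes=10)
        assert np.allclose(m.phi.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(m.theta.sum(axis=1), 1.0, atol=1e-6)
        assert (m.phi >= 0).all() and (m.theta >= 0).all()

    def test_k_preconditions(self):
        _, d, bow = self._tiny()
        with pytest.raises(ValueError):
            tm.train_lda(bow, d, K=1)
        with pytest.raises(ValueError):
            tm.train_lda(bow, d, K=len(bow) + 1)

    def test_disjoint_single_word_docs_are_one_hot(self):
        """Each document repeats one distinct word; at K = #words every
        theta row concentrates on one topic."""
        _, d, bow = self._tiny(K=4)
        m = tm.train_lda(bow, d, K=4, seed=1, passes=25)
        assert (m.theta.max(axis=1) > 0.9).all()
        # and the induced partition matches the word partition
        doms = [tm.dominant_topic(row)[0] for row in m.theta]
        by_word = {}
        for doc_id, t in zip(m.doc_ids, doms):
            by_word.setdefault(doc_id.split("_")[0], set()).add(t)
        assert all(len(ts) == 1 for ts in by_word.values())

    def test_reproducible(self):
        _, d, bow = self._tiny()
        m1 = tm.train_lda(bow, d, K=3, seed=5, passes=5)
        m2 = tm.train_lda(bow, d, K=3, seed=5, passes=5)
        assert np.array_equal(m1.phi, m2.phi)

    def test_signature_recovery(self, recovery_lda, recovery_small):
        """At K = K* the learned top-10 word sets match planted signatures."""
        from scipy.optimize import linear_sum_assignment

        _, truth = recovery_small
        tops = [set(w for w, _ in tm.top_keywords(recovery_lda, t, 10)) for t in range(5)]
        C = np.zeros((5, 5))
        for i, ts in enumerate(tops):
            for j, sig in enumerate(truth.signatures):
                C[i, j] = len(ts & sig) / 10
        r, c = linear_sum_assignment(-C)
        assert C[r, c].mean() >= 0.6


class TestTopicOverlap:
    def _model(self, phi):
        V = np.asarray(phi).shape[1]
        return make_topic_model(phi, np.ones((1, np.asarray(phi).shape[0])),
                                [f"w{i}" for i in range(V)])

    def test_identical_topics(self):
        row = np.full(12, 1 / 12)
        assert tm.topic_overlap(self._model([row, row]), top_n=10) == pytest.approx(1.0)

    def test_disjoint_topics(self):
        a = np.r_[np.full(10, 0.1), np.zeros(10)]
        b = np.r_[np.zeros(10), np.full(10, 0.1)]
        assert tm.topic_overlap(self._model([a, b]), top_n=10) == pytest.approx(0.0)

    def test_hand_enumerated_three_topics(self):
        """Pairwise top-10 intersections of sizes {5, 0, 5} average to 1/3."""
        # topics A and B share words 0-4; topic C shares words 5-9 with B, none with A
        V = 25
        A = np.zeros(V); A[0:5] = 0.12; A[10:15] = 0.08
        B = np.zeros(V); B[0:5] = 0.12; B[5:10] = 0.08
        C = np.zeros(V); C[5:10] = 0.12; C[15:20] = 0.08
        for row in (A, B, C):
            row /= row.sum()
        got = tm.topic_overlap(self._model([A, B, C]), top_n=10)
        assert got == pytest.approx((0.5 + 0.0 + 0.5) / 3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        phi = rng.dirichlet(np.ones(30), size=4)
        m = self._model(phi)
        perm = self._model(phi[[2, 0, 3, 1]])
        assert tm.topic_overlap(perm) == pytest.approx(tm.topic_overlap(m))

    def test_top_n_bound(self):
        with pytest.raises(ValueError):
            tm.topic_overlap(self._model(np.ones((2, 5)) / 5), top_n=6)


class TestDominantTopic:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ((0.1, 0.7, 0.2), (1, 0.7)),
            ((0.5, 0.5), (0, 0.5)),          # tie -> lowest id
            (tuple([1 / 9] * 9), (0, 1 / 9)),  # uniform -> topic 0
        ],
    )
    def test_argmax_with_tie_rule(self, row, expected):
        idx, p = tm.dominant_topic(np.array(row))
        assert idx == expected[0]
        assert p == pytest.approx(expected[1])

    def test_empty_vector(self):
        with pytest.raises(ValueError):
            tm.dominant_topic(np.array([]))


class TestTopKeywords:
    def test_mass_ordering(self):
        phi = np.array([[0.9, 0.05, 0.05]])
        m = make_topic_model(phi, np.ones((1, 1)), ["virtual", "x", "y"])
        assert tm.top_keywords(m, 0, 1)[0] == ("virtual", pytest.approx(0.9))

    def test_n_exceeds_vocabulary(self):
        m = make_topic_model(np.ones((1, 3)) / 3, np.ones((1, 1)), ["a", "b", "c"])
        with pytest.raises(ValueError):
            tm.top_keywords(m, 0, 4)

    def test_bad_topic_id(self):
        m = make_topic_model(np.ones((1, 3)) / 3, np.ones((1, 1)), ["a", "b", "c"])
        with pytest.raises(IndexError):
            tm.top_keywords(m, 5)


class TestCoherence:
    def test_cooccurring_words_score_higher(self):
        corpus = docs_from([["a", "b"]] * 20 + [["c"]] * 10 + [["d"]] * 10)
        scorer = tm.CoherenceScorer(corpus, measure="npmi", window_size=5)
        assert scorer.topic_score(["a", "b"]) > scorer.topic_score(["c", "d"])

    def test_umass_variant_runs(self):
        corpus = docs_from([["a", "b", "c"]] * 5 + [["a", "d"]] * 5)
        scorer = tm.CoherenceScorer(corpus, measure="umass")
        assert np.isfinite(scorer.topic_score(["a", "b", "d"]))


class TestEvaluateTopicRange:
    def test_single_candidate(self):
        corpus = docs_from([["a", "b"] * 10, ["c", "d"] * 10, ["a", "c"] * 10])
        d = tm.build_dictionary(corpus, min_doc_count=1, max_doc_fraction=1.0)
        bow, _ = tm.to_bow(corpus, d)
        rep = tm.evaluate_topic_range(bow, d, corpus, K_range=[2], seed=0, passes=5, top_n=3)
        assert len(rep.rows) == 1
        assert rep.chosen_K == 2
        assert rep.rows[0]["log_perplexity"] <= 0
        assert 0 <= rep.rows[0]["topic_overlap"] <= 1

    def test_forced_k_override(self):
        corpus = docs_from([["a", "b"] * 5, ["c", "d"] * 5, ["a", "d"] * 5, ["b", "c"] * 5])
        d = tm.build_dictionary(corpus, min_doc_count=1, max_doc_fraction=1.0)
        bow, _ = tm.to_bow(corpus, d)
        rep = tm.evaluate_topic_range(bow, d, corpus, K_range=[2, 3], seed=0, passes=3,
                                      top_n=2, forced_k=3)
        assert rep.chosen_K == 3 and rep.selection_rule == "forced"
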