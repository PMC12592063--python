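"""Shared fixtures: a small planted-topic corpus and models trained on it.

Session-scoped so the expensive artifacts (embedding, LDA) are trained once
and shared by the module test files.  Sizes are deliberately small; the
statistical acceptance checks in test_acceptance.py use the full preset
conditions.
"""
from __future__ import annotations

import numpy as np
import pytest

from themetrace import corpus_io, embedding as emb, fusion, synthetic, topic_model as tm


@pytest.fixture(scope="session")
def recovery_small():
    """300-document 'recovery' corpus (5 planted topics) with ground truth."""
    spec = synthetic.preset_scenario("recovery", seed=1, n_docs=300)
    records, truth = synthetic.generate_corpus(spec)
    return records, truth


@pytest.fixture(scope="session")
def recovery_docs(recovery_small):
    records, _ = recovery_small
    docs, _flagged = corpus_io.preprocess_corpus(records, corpus_io.load_stopwords())
    return docs


@pytest.fixture(scope="session")
def recovery_emb(recovery_docs):
    return emb.train_embedding(
        recovery_docs, dim=32, window=5, seed=7, opts=emb.TrainingOptions(epochs=5)
    )


@pytest.fixture(scope="session")
def recovery_lda(recovery_docs):
    d = tm.build_dictionary(recovery_docs)
    bow, _ = tm.to_bow(recovery_docs, d)
    return tm.train_lda(bow, d, K=5, seed=11, passes=15)


@pytest.fixture(scope="session")
def recovery_fused(recovery_lda, recovery_emb):
    return fusion.fuse_corpus(recovery_lda, recovery_emb)


def make_embedding(vectors: dict[str, list[float]], window: int = 2) -> emb.EmbeddingModel:
    """Hand-set embedding model for exact-arithmetic tests."""
    words = tuple(sorted(vectors))
    matrix = np.array([vectors[w] for w in words], dtype=float)
    return emb.EmbeddingModel(words, matrix, matrix.shape[1], window, {"algorithm": "fixture"})


def make_topic_model(phi: np.ndarray, theta: np.ndarray, words: list[str],
                     doc_ids: list[str] | None = None) -> tm.TopicModelResult:
    """Assemble a TopicModelResult with prescribed phi/theta for unit tests."""
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    dictionary = tm.FilteredDictionary(
        tuple(words), tuple([1] * len(words)), max(len(theta), 1), 1, 1.0
    )
    return tm.TopicModelResult(
        K=phi.shape[0],
        phi=phi,
        theta=theta,
        doc_ids=tuple(doc_ids or [f"d{i}" for i in range(theta.shape[0])]),
        dictionary=dictionary,
        seed=0,
        priors={},
        log_perplexity=0.0,
    )
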