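"""Fused semantic vectors: topics and documents as embedding-space points.

A topic vector is the probability-weighted average of the embeddings of the
topic's top keywords (weights are the LDA word probabilities, renormalized
over the keywords actually present in the embedding vocabulary).  A document
vector is the theta-weighted average of its top dominant topics' vectors
(at most five, weights renormalized over the selected set).  Every document
vector therefore lies in the convex hull of the topic vectors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .embedding import EmbeddingModel
from .errors import FusionError
from .topic_model import TopicModelResult, top_keywords

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopicVector:
    topic_id: int
    vector: np.ndarray
    used_keywords: tuple[tuple[str, float], ...]   # (word, normalized weight)
    dropped_keywords: tuple[str, ...]              # absent from embedding vocabulary


@dataclass(frozen=True)
class DocumentVector:
    doc_id: str
    vector: np.ndarray
    contributing_topics: tuple[tuple[int, float], ...]  # (topic id, normalized weight)


def topic_vector(
    model: TopicModelResult,
    emb: EmbeddingModel,
    topic_id: int,
    top_n: int = 10,
) -> TopicVector:
    """Convex combination of the topic's in-vocabulary top-keyword embeddings."""
    keywords = top_keywords(model, topic_id, min(top_n, len(model.dictionary)))
    used = [(w, p) for w, p in keywords if w in emb]
    dropped = tuple(w for w, _ in keywords if w not in emb)
    if not used:
        raise FusionError(f"all top-{top_n} keywords of topic {topic_id} are out of vocabulary")
    total = sum(p for _, p in used)
    weights = [(w, p / total) for w, p in used]
    vec = np.zeros(emb.dim)
    for w, wt in weights:
        vec += wt * emb[w]
    return TopicVector(topic_id, vec, tuple(weights), dropped)


def document_vector(
    theta_row: np.ndarray,
    topic_vectors: Sequence[TopicVector],
    top_m: int = 5,
    doc_id: str = "",
) -> DocumentVector:
    """Weighted average of the document's top ``top_m`` topics' vectors.

    Topics are ranked by theta (ties toward the lower id); weights are
    renormalized over the selected set.  When K < top_m, all topics are used.
    """
    theta_row = np.asarray(theta_row, dtype=float)
    if theta_row.size == 0:
        raise FusionError("empty topic distribution")
    if theta_row.size != len(topic_vectors):
        raise FusionError("theta length does not match the number of topic vectors")
    m = min(top_m, theta_row.size)
    order = np.lexsort((np.arange(theta_row.size), -theta_row))[:m]
    total = float(theta_row[order].sum())
    if total <= 0:
        raise FusionError(f"document {doc_id!r}: no positive topic weight among the top {m}")
    contrib = tuple((int(t), float(theta_row[t] / total)) for t in order)
    vec = np.zeros(topic_vectors[0].vector.shape)
    for t, wt in contrib:
        vec += wt * topic_vectors[t].vector
    return DocumentVector(doc_id, vec, contrib)


def fuse_corpus(
    model: TopicModelResult,
    emb: EmbeddingModel,
    top_n: int = 10,
    top_m: int = 5,
) -> tuple[list[DocumentVector], list[TopicVector]]:
    """One fused vector per modeled document (empty-bag documents were
    already dropped at the bag-of-words stage)."""
    tvecs = [topic_vector(model, emb, t, top_n) for t in range(model.K)]
    n_dropped = sum(len(tv.dropped_keywords) for tv in tvecs)
    if n_dropped:
        logger.info("fusion dropped %d out-of-vocabulary keywords across %d topics", n_dropped, model.K)
    dvecs = [
        document_vector(model.theta[i], tvecs, top_m=top_m, doc_id=doc_id)
        for i, doc_id in enumerate(model.doc_ids)
    ]
    return dvecs, tvecs
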