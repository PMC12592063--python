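"""Per-phase k-means over standardized fused vectors, with silhouette-based
selection of the cluster count and per-cluster profiling.

Within each time phase the fused document vectors are z-scored per dimension
(population standard deviation), k-means is run for each candidate k, and the
k maximizing the mean silhouette is kept.  Each cluster is then profiled:
its dominant topic (argmax of the mean theta over members), its
representative document (closest member to the standardized centroid), and
topic-weighted keywords (each member contributes its theta-weighted mixture
of topic-word distributions).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .fusion import DocumentVector
from .fingerprint import stable_seed
from .topic_model import TopicModelResult

logger = logging.getLogger(__name__)

#: Phases smaller than this are reported as a single cluster.
MIN_PHASE_SIZE = 10


@dataclass
class PhaseClustering:
    phase: str
    k: int
    doc_ids: tuple[str, ...]
    labels: np.ndarray                 # cluster id per document
    centroids_std: np.ndarray          # k x dim, standardized space
    centroids_raw: np.ndarray          # k x dim, member means in raw fused space
    silhouette_by_k: dict[int, float]
    seed: int
    std_matrix: np.ndarray = field(repr=False, default=None)
    raw_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def assignments(self) -> dict[str, int]:
        return {d: int(c) for d, c in zip(self.doc_ids, self.labels)}

    def members(self, cluster_id: int) -> list[int]:
        return [i for i, c in enumerate(self.labels) if c == cluster_id]


@dataclass(frozen=True)
class ClusterProfile:
    phase: str
    cluster_id: int
    size: int
    dominant_topic: tuple[int, float]
    representative_doc: str
    keywords: tuple[tuple[str, float], ...]
    mean_topic_weights: np.ndarray


def standardize(vectors: Sequence[DocumentVector] | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each dimension using the population standard deviation.

    Zero-variance dimensions are left at 0 with a warning.  Returns
    ``(Z, mean, sd)``.
    """
    X = np.asarray([v.vector for v in vectors]) if not isinstance(vectors, np.ndarray) else np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize needs at least 2 vectors")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population convention (divide by n)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance dimensions left at 0", stacklevel=2)
    safe = np.where(zero, 1.0, sd)
    Z = (X - mean) / safe
    Z[:, zero] = 0.0
    return Z, mean, sd


def _kmeans(Z: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, max_iter=300, tol=1e-6)
    km.fit(Z)
    return km


def select_k(
    std_matrix: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, dict[int, float]]:
    """Mean silhouette for each candidate k; argmax wins, ties to smaller k.

    Candidates with k >= n points are skipped with a warning.
    """
    n = std_matrix.shape[0]
    scores: dict[int, float] = {}
    for k in k_range:
        if k < 2:
            continue
        if k >= n:
            warnings.warn(f"skipping k={k}: only {n} points", stacklevel=2)
            continue
        km = _kmeans(std_matrix, k, seed, n_init)
        if len(np.unique(km.labels_)) < 2:
            warnings.warn(f"skipping k={k}: degenerate single-cluster solution", stacklevel=2)
            continue
        scores[k] = float(silhouette_score(std_matrix, km.labels_, metric="euclidean"))
    if not scores:
        raise ValueError("no evaluable k in range")
    best = min(scores, key=lambda k: (-scores[k], k))
    return best, scores


def cluster_phase(
    vectors: Sequence[DocumentVector],
    k: int,
    seed: int = 0,
    phase: str = "",
    n_init: int = 10,
    silhouette_by_k: dict[int, float] | None = None,
) -> PhaseClustering:
    """K-means the phase's standardized vectors (best of ``n_init`` restarts).

    Raw-space centroids are recomputed as unweighted member means of the
    original fused vectors, because per-phase z-scores are not comparable
    across phases.
    """
    n = len(vectors)
    if k < 1 or (k >= n and k != 1):
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    X = np.asarray([v.vector for v in vectors])
    doc_ids = tuple(v.doc_id for v in vectors)
    if k == 1:
        Z = np.zeros_like(X)
        labels = np.zeros(n, dtype=int)
        centroids_std = np.zeros((1, X.shape[1]))
    else:
        Z, _, _ = standardize(vectors)
        km = _kmeans(Z, k, seed, n_init)
        labels = km.labels_.astype(int)
        centroids_std = km.cluster_centers_
    centroids_raw = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    return PhaseClustering(
        phase=phase,
        k=k,
        doc_ids=doc_ids,
        labels=labels,
        centroids_std=centroids_std,
        centroids_raw=centroids_raw,
        silhouette_by_k=dict(silhouette_by_k or {}),
        seed=seed,
        std_matrix=Z,
        raw_matrix=X,
    )


def cluster_phase_auto(
    vectors: Sequence[DocumentVector],
    phase: str = "",
    k_range: Sequence[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
    min_phase_size: int = MIN_PHASE_SIZE,
) -> PhaseClustering:
    """Silhouette-select k, then cluster.  Phases below ``min_phase_size``
    documents are reported as a single cluster with a warning."""
    if len(vectors) < min_phase_size:
        warnings.warn(
            f"phase {phase!r} has only {len(vectors)} documents; reporting a single cluster",
            stacklevel=2,
        )
        return cluster_phase(vectors, 1, seed=seed, phase=phase, n_init=n_init)
    Z, _, _ = standardize(vectors)
    k, scores = select_k(Z, k_range=k_range, seed=stable_seed(seed, f"select-k-{phase}"), n_init=n_init)
    return cluster_phase(vectors, k, seed=seed, phase=phase, n_init=n_init, silhouette_by_k=scores)


def profile_cluster(
    pc: PhaseClustering,
    cluster_id: int,
    model: TopicModelResult,
    keyword_n: int = 10,
) -> ClusterProfile:
    """Profile one cluster: mean theta, dominant topic, representative
    document, and topic-weighted keywords.

    The representative is the member closest (Euclidean, standardized space)
    to the cluster centroid, ties to the lexicographically smallest doc id.
    Keywords come from the member-averaged word distribution
    mean_d(theta_d @ phi), descending, ties toward the lower word id.
    """
    if not (0 <= cluster_id < pc.k):
        raise IndexError(f"cluster id {cluster_id} out of range [0, {pc.k})")
    members = pc.members(cluster_id)
    if not members:
        raise IndexError(f"cluster {cluster_id} is empty")
    thetas = np.vstack([model.theta_for(pc.doc_ids[i]) for i in members])
    mean_theta = thetas.mean(axis=0)
    dom = int(np.argmax(mean_theta))

    dists = np.linalg.norm(pc.std_matrix[members] - pc.centroids_std[cluster_id], axis=1)
    best = min(range(len(members)), key=lambda j: (dists[j], pc.doc_ids[members[j]]))
    representative = pc.doc_ids[members[best]]

    word_dist = mean_theta @ model.phi  # member-average of theta_d @ phi
    n = min(keyword_n, word_dist.size)
    order = np.lexsort((np.arange(word_dist.size), -word_dist))[:n]
    keywords = tuple((model.dictionary.words[i], float(word_dist[i])) for i in order)

    return ClusterProfile(
        phase=pc.phase,
        cluster_id=cluster_id,
        size=len(members),
        dominant_topic=(dom, float(mean_theta[dom])),
        representative_doc=representative,
        keywords=keywords,
        mean_topic_weights=mean_theta,
    )


def profile_phase(pc: PhaseClustering, model: TopicModelResult, keyword_n: int = 10) -> list[ClusterProfile]:
    return [profile_cluster(pc, c, model, keyword_n) for c in range(pc.k)]


def cluster_topic_matrix(profiles: Sequence[ClusterProfile]) -> np.ndarray:
    """Clusters x K matrix of mean topic weights; each row sums to 1."""
    if not profiles:
        raise ValueError("no profiles supplied")
    return np.vstack([p.mean_topic_weights for p in sorted(profiles, key=lambda p: p.cluster_id)])
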