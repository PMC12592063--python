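"""Word embeddings: skip-gram training, pair coherence, grid search, neighbors.

The trainer is a skip-gram model with negative sampling (SGNS): for each
(center, context) pair drawn from a dynamic window, the dot product of the
input vector of the center word and the output vector of the context word is
pushed up, while dots against ``negative`` noise words sampled from the
unigram distribution raised to 3/4 are pushed down.  Training is plain SGD
with a linearly decaying learning rate and is bit-reproducible from the seed
(single worker by construction).

Model quality is audited by *pair coherence* — the mean cosine similarity
over a user-supplied list of word pairs known to be semantically related in
the domain — and by nearest-neighbor inspection of anchor words.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .corpus_io import TokenizedDocument
from .errors import CoverageError, TrainingError

__all__ = [
    "EmbeddingModel",
    "CoherencePairSet",
    "GridSearchReport",
    "TrainingOptions",
    "train_embedding",
    "pair_coherence",
    "pair_coherence_report",
    "grid_search",
    "nearest_neighbors",
    "default_pair_set",
    "save_word2vec_format",
    "load_word2vec_format",
]


@dataclass(frozen=True)
class TrainingOptions:
    epochs: int = 50
    min_count: int = 2
    negative: int = 5
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    batch_size: int = 4096


@dataclass
class EmbeddingModel:
    """Trained embedding: a vocabulary and one dense vector per word."""

    words: tuple[str, ...]
    matrix: np.ndarray  # |V| x dim
    dim: int
    window: int
    training_meta: dict

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __getitem__(self, word: str) -> np.ndarray:
        try:
            return self.matrix[self._index[word]]
        except KeyError:
            raise LookupError(f"word {word!r} not in embedding vocabulary") from None


@dataclass(frozen=True)
class CoherencePairSet:
    """Word pairs exemplifying meaningful semantic relations in the domain."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("CoherencePairSet must be non-empty")


def default_pair_set() -> CoherencePairSet:
    """Convenience pairs drawn from the public-speaking-anxiety domain's
    anchor vocabulary.  Coherence values are corpus-dependent; replace this
    set for any other domain."""
    return CoherencePairSet(
        pairs=(
            ("public", "speaking"),
            ("communication", "apprehension"),
            ("virtual", "exposure"),
            ("speech", "anxiety"),
            ("social", "phobia"),
            ("stress", "cortisol"),
            ("scale", "validity"),
            ("language", "learning"),
            ("fear", "anxiety"),
            ("treatment", "therapy"),
        )
    )


@dataclass
class GridSearchReport:
    """One row per (dim, window) cell, sorted by coherence descending."""

    rows: list[dict]  # dim, window, coherence, vocab_coverage, error
    best_config: tuple[int, int]


# ---------------------------------------------------------------------------
# training


def _build_vocab(corpus: Sequence[TokenizedDocument], min_count: int):
    counts: dict[str, int] = {}
    for doc in corpus:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    # deterministic ordering: frequency descending, then lexicographic
    kept = sorted((w for w, c in counts.items() if c >= min_count), key=lambda w: (-counts[w], w))
    return kept, counts


def _generate_pairs(encoded: list[np.ndarray], window: int, rng: np.random.Generator):
    """All (center, context) pairs of one epoch under per-center dynamic windows."""
    centers, contexts = [], []
    for ids in encoded:
        n = len(ids)
        if n < 2:
            continue
        b = rng.integers(1, window + 1, size=n)
        for d in range(1, window + 1):
            if d >= n:
                break
            left, right = ids[:-d], ids[d:]
            m = b[:-d] >= d  # left word is the center, right word its context
            centers.append(left[m]); contexts.append(right[m])
            m = b[d:] >= d   # right word is the center, left word its context
            centers.append(right[m]); contexts.append(left[m])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


@njit(cache=True)
def _sgd_pass(w_in, w_out, centers, contexts, negatives, lr0, lr_min, processed0, total):
    """One sequential SGD pass over shuffled (center, context) pairs.

    Classic word2vec update: the positive context's output vector is pulled
    toward the center's input vector, the sampled noise words are pushed
    away; the learning rate decays linearly over the whole training run.
    """
    dim = w_in.shape[1]
    n_neg = negatives.shape[1]
    gin = np.empty(dim)
    for i in range(centers.shape[0]):
        lr = lr0 * (1.0 - (processed0 + i) / total)
        if lr < lr_min:
            lr = lr_min
        c = centers[i]
        o = contexts[i]
        for d in range(dim):
            gin[d] = 0.0
        z = 0.0
        for d in range(dim):
            z += w_in[c, d] * w_out[o, d]
        if z > 30.0:
            z = 30.0
        elif z < -30.0:
            z = -30.0
        g = (1.0 - 1.0 / (1.0 + np.exp(-z))) * lr
        for d in range(dim):
            gin[d] += g * w_out[o, d]
            w_out[o, d] += g * w_in[c, d]
        for k in range(n_neg):
            nidx = negatives[i, k]
            if nidx == o:
                continue
            z = 0.0
            for d in range(dim):
                z += w_in[c, d] * w_out[nidx, d]
            if z > 30.0:
                z = 30.0
            elif z < -30.0:
                z = -30.0
            g = (-1.0 / (1.0 + np.exp(-z))) * lr
            for d in range(dim):
                gin[d] += g * w_out[nidx, d]
                w_out[nidx, d] += g * w_in[c, d]
        for d in range(dim):
            w_in[c, d] += gin[d]
    return processed0 + centers.shape[0]


def train_embedding(
    corpus: Sequence[TokenizedDocument],
    dim: int,
    window: int,
    seed: int = 0,
    opts: TrainingOptions | None = None,
) -> EmbeddingModel:
    """Train SGNS embeddings on a cleaned corpus.

    Every word occurring at least ``opts.min_count`` times receives a
    ``dim``-length vector.  Reproducible given the seed (single worker).
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if dim < 2:
        raise ValueError(f"dim must be >= 2, got {dim}")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    opts = opts or TrainingOptions()

    words, counts = _build_vocab(corpus, opts.min_count)
    if not words:
        raise TrainingError(f"empty effective vocabulary at min_count={opts.min_count}")
    index = {w: i for i, w in enumerate(words)}
    encoded = [
        np.array([index[t] for t in doc.tokens if t in index], dtype=np.int64) for doc in corpus
    ]

    rng = np.random.default_rng(seed)
    V = len(words)
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))

    freq = np.array([counts[w] for w in words], dtype=float) ** 0.75
    noise_cum = np.cumsum(freq / freq.sum())

    lr0, lr_min = opts.initial_lr, opts.min_lr
    processed = 0
    total_est = None  # pair count of epoch 1 sets the linear lr schedule
    for _epoch in range(opts.epochs):
        centers, contexts = _generate_pairs(encoded, window, rng)
        if centers.size == 0:
            raise TrainingError("corpus yields no (center, context) pairs")
        if total_est is None:
            total_est = centers.size * opts.epochs
        order = rng.permutation(centers.size)
        centers, contexts = centers[order], contexts[order]
        # unigram^(3/4) noise words via inverse-CDF sampling
        neg = np.searchsorted(
            noise_cum, rng.random((centers.size, opts.negative))
        ).astype(np.int64)
        processed = _sgd_pass(
            w_in, w_out, centers, contexts, neg, lr0, lr_min, processed, total_est
        )

    meta = {
        "algorithm": "sgns",
        "epochs": opts.epochs,
        "min_count": opts.min_count,
        "negative": opts.negative,
        "seed": seed,
        "dim": dim,
        "window": window,
        "workers": 1,
    }
    return EmbeddingModel(tuple(words), w_in, dim, window, meta)


# ---------------------------------------------------------------------------
# evaluation


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def pair_coherence_report(model: EmbeddingModel, pairs: CoherencePairSet) -> dict:
    """Coherence plus coverage bookkeeping.

    Returns ``{"coherence", "n_evaluated", "n_skipped", "vocab_coverage"}``
    where coverage is the fraction of distinct pair words present in the
    vocabulary.  Pairs with an out-of-vocabulary member are skipped, never
    zero-scored (zero-scoring would conflate coverage with coherence).
    """
    sims, skipped = [], 0
    for a, b in pairs.pairs:
        if a in model and b in model:
            sims.append(_cosine(model[a], model[b]))
        else:
            skipped += 1
    words = {w for p in pairs.pairs for w in p}
    coverage = sum(1 for w in words if w in model) / len(words)
    if not sims:
        raise CoverageError("no coherence pair has both words in the vocabulary")
    return {
        "coherence": float(np.mean(sims)),
        "n_evaluated": len(sims),
        "n_skipped": skipped,
        "vocab_coverage": coverage,
    }


def pair_coherence(model: EmbeddingModel, pairs: CoherencePairSet) -> float:
    """Unweighted mean cosine similarity over the evaluable pairs, in [-1, 1]."""
    return pair_coherence_report(model, pairs)["coherence"]


def grid_search(
    corpus: Sequence[TokenizedDocument],
    dims: Sequence[int],
    windows: Sequence[int],
    pairs: CoherencePairSet,
    seed: int = 0,
    opts: TrainingOptions | None = None,
) -> GridSearchReport:
    """Train one model per (dim, window) cell and rank cells by coherence.

    Ties break toward the smaller dim, then the smaller window.  A failing
    cell is annotated in its row instead of aborting the grid.
    """
    if not dims or not windows:
        raise ValueError("dims and windows must be non-empty")
    rows = []
    for dim in dims:
        for window in windows:
            row: dict = {"dim": dim, "window": window, "coherence": math.nan,
                         "vocab_coverage": math.nan, "error": ""}
            try:
                model = train_embedding(corpus, dim, window, seed=seed, opts=opts)
                rep = pair_coherence_report(model, pairs)
                row["coherence"] = rep["coherence"]
                row["vocab_coverage"] = rep["vocab_coverage"]
            except Exception as exc:  # annotate, don't abort
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    valid = [r for r in rows if not r["error"]]
    if not valid:
        raise TrainingError("every grid cell failed: " + "; ".join(r["error"] for r in rows))
    rows.sort(key=lambda r: (-(r["coherence"]) if not r["error"] else math.inf, r["dim"], r["window"]))
    best = max(valid, key=lambda r: (r["coherence"], -r["dim"], -r["window"]))
    return GridSearchReport(rows=rows, best_config=(best["dim"], best["window"]))


def nearest_neighbors(model: EmbeddingModel, word: str, n: int) -> list[tuple[str, float]]:
    """The ``n`` highest-cosine vocabulary words, excluding the query.

    Descending by cosine; exact ties break lexicographically.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if word not in model:
        raise LookupError(f"word {word!r} not in embedding vocabulary")
    q = model[word]
    qn = np.linalg.norm(q)
    norms = np.linalg.norm(model.matrix, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sims = model.matrix @ q / (safe * (qn if qn else 1.0))
    sims[norms == 0] = 0.0
    scored = [(w, float(s)) for w, s in zip(model.words, sims) if w != word]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:n]


# ---------------------------------------------------------------------------
# persistence


def save_word2vec_format(model: EmbeddingModel, path: str | Path) -> None:
    """Write the standard word2vec text format plus a sidecar meta JSON."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(model.words)} {model.dim}\n")
        for w, vec in zip(model.words, model.matrix):
            fh.write(w + " " + " ".join(repr(float(x)) for x in vec) + "\n")
    with open(path.with_suffix(path.suffix + ".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(model.training_meta, fh, indent=2, sort_keys=True)


def load_word2vec_format(path: str | Path) -> EmbeddingModel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        v, dim = int(header[0]), int(header[1])
        words, vecs = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            words.append(parts[0])
            vecs.append([float(x) for x in parts[1:]])
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    matrix = np.asarray(vecs, dtype=float)
    assert matrix.shape == (v, dim)
    return EmbeddingModel(tuple(words), matrix, dim, int(meta.get("window", 0)), meta)
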