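"""Dictionary filtering, bag-of-words, LDA training, and model selection.

LDA treats each document as a mixture over K latent topics (rows of theta)
and each topic as a distribution over the filtered vocabulary (rows of phi).
Candidate topic counts are scored on three axes: coherence of each topic's
top words (sliding-window NPMI over the cleaned corpus by default), the
per-word variational log-likelihood bound ("log perplexity", <= 0), and
*topic overlap* — the mean pairwise fraction of shared top-N words, where
lower means more distinct topics.
"""
from __future__ import annotations

import csv
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from .corpus_io import TokenizedDocument
from .errors import FilterError
from .fingerprint import stable_seed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilteredDictionary:
    """Word <-> integer-id bijection over the filtered vocabulary.

    Ids are assigned in sorted word order, so the mapping is a pure function
    of the retained vocabulary.
    """

    words: tuple[str, ...]  # sorted; index == id
    doc_freq: tuple[int, ...]
    n_docs: int
    min_doc_count: int
    max_doc_fraction: float

    def __post_init__(self):
        object.__setattr__(self, "_index", {w: i for i, w in enumerate(self.words)})

    def __len__(self) -> int:
        return len(self.words)

    def id_for(self, word: str) -> int:
        return self._index[word]

    def __contains__(self, word: str) -> bool:
        return word in self._index


@dataclass(frozen=True)
class BowDocument:
    doc_id: str
    entries: tuple[tuple[int, int], ...]  # (word_id, count), count >= 1

    @property
    def n_tokens(self) -> int:
        return sum(c for _, c in self.entries)


@dataclass
class TopicModelResult:
    """A trained LDA model: phi (K x V) and theta (D x K), plus provenance."""

    K: int
    phi: np.ndarray
    theta: np.ndarray
    doc_ids: tuple[str, ...]
    dictionary: FilteredDictionary
    seed: int
    priors: dict
    log_perplexity: float

    def theta_for(self, doc_id: str) -> np.ndarray:
        if not hasattr(self, "_doc_index"):
            self._doc_index = {d: i for i, d in enumerate(self.doc_ids)}
        return self.theta[self._doc_index[doc_id]]


@dataclass
class ModelSelectionReport:
    rows: list[dict]  # K, coherence, log_perplexity, topic_overlap, error
    chosen_K: int
    selection_rule: str


# ---------------------------------------------------------------------------
# dictionary and bag-of-words


def build_dictionary(
    corpus: Sequence[TokenizedDocument],
    min_doc_count: int = 3,
    max_doc_fraction: float = 0.5,
) -> FilteredDictionary:
    """Build the filtered dictionary.

    A word is retained iff it occurs in at least ``min_doc_count`` documents
    AND in at most ``max_doc_fraction`` of them (both boundaries inclusive).
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if not (0 < max_doc_fraction <= 1):
        raise ValueError("max_doc_fraction must lie in (0, 1]")
    df: dict[str, int] = {}
    for doc in corpus:
        for w in set(doc.tokens):
            df[w] = df.get(w, 0) + 1
    n = len(corpus)
    kept = sorted(w for w, c in df.items() if c >= min_doc_count and c / n <= max_doc_fraction)
    if not kept:
        raise FilterError(
            f"no word survived filtering (min_doc_count={min_doc_count}, "
            f"max_doc_fraction={max_doc_fraction})"
        )
    return FilteredDictionary(tuple(kept), tuple(df[w] for w in kept), n, min_doc_count, max_doc_fraction)


def to_bow(
    corpus: Sequence[TokenizedDocument], dictionary: FilteredDictionary
) -> tuple[list[BowDocument], list[str]]:
    """Convert documents to sparse bag-of-words rows.

    Documents whose bag is empty after filtering are dropped (their ids are
    returned separately and the count logged); they cannot inform the model
    and their fused vectors would be undefined.
    """
    bows, dropped = [], []
    for doc in corpus:
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            if tok in dictionary:
                i = dictionary.id_for(tok)
                counts[i] = counts.get(i, 0) + 1
        if counts:
            bows.append(BowDocument(doc.doc_id, tuple(sorted(counts.items()))))
        else:
            dropped.append(doc.doc_id)
    if dropped:
        logger.warning("%d documents had empty bag-of-words after filtering", len(dropped))
    return bows, dropped


def _bow_matrix(bow: Sequence[BowDocument], n_words: int) -> sparse.csr_matrix:
    rows, cols, data = [], [], []
    for i, doc in enumerate(bow):
        for wid, count in doc.entries:
            rows.append(i); cols.append(wid); data.append(count)
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(bow), n_words))


# ---------------------------------------------------------------------------
# LDA


def train_lda(
    bow: Sequence[BowDocument],
    dictionary: FilteredDictionary,
    K: int,
    seed: int = 0,
    priors: dict | None = None,
    passes: int = 20,
    n_init: int = 3,
) -> TopicModelResult:
    """Train a K-topic LDA model (batch variational Bayes).

    Symmetric priors default to 1/K on both the document-topic and
    topic-word sides; ``passes`` is the number of full variational passes.
    Variational inference lands in local optima, so ``n_init`` independent
    restarts are fitted and the one with the highest per-word likelihood
    bound kept (the k-means restart logic, applied to LDA).  phi and theta
    rows are normalized probability vectors; the result is deterministic
    given ``seed``.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if not bow:
        raise ValueError("bag-of-words corpus is empty")
    if K > len(bow):
        raise ValueError(f"K={K} exceeds the number of documents ({len(bow)})")
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    priors = dict(priors or {})
    doc_topic_prior = priors.get("alpha", 1.0 / K)
    topic_word_prior = priors.get("eta", 1.0 / K)

    X = _bow_matrix(bow, len(dictionary))
    total_tokens = int(X.sum())
    best = None
    for restart in range(n_init):
        lda = LatentDirichletAllocation(
            n_components=K,
            doc_topic_prior=doc_topic_prior,
            topic_word_prior=topic_word_prior,
            learning_method="batch",
            max_iter=passes,
            random_state=seed if restart == 0 else stable_seed(seed, f"lda-restart{restart}"),
        )
        theta_r = lda.fit_transform(X)
        bound = float(lda.score(X)) / total_tokens  # per-word ELBO, <= 0 in practice
        if best is None or bound > best[0]:
            best = (bound, lda, theta_r)
    log_perp, lda, theta = best
    theta = theta / theta.sum(axis=1, keepdims=True)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    return TopicModelResult(
        K=K,
        phi=phi,
        theta=theta,
        doc_ids=tuple(d.doc_id for d in bow),
        dictionary=dictionary,
        seed=seed,
        priors={"alpha": doc_topic_prior, "eta": topic_word_prior, "passes": passes},
        log_perplexity=log_perp,
    )


def _top_word_ids(phi_row: np.ndarray, n: int) -> np.ndarray:
    """Ids of the n highest-probability words; ties break toward lower id."""
    order = np.lexsort((np.arange(phi_row.size), -phi_row))
    return order[:n]


def top_keywords(model: TopicModelResult, topic_id: int, n: int = 10) -> list[tuple[str, float]]:
    """Top-n (word, probability) for one topic, descending, ties by word id."""
    if not (0 <= topic_id < model.K):
        raise IndexError(f"topic id {topic_id} out of range [0, {model.K})")
    if n > len(model.dictionary):
        raise ValueError(f"n={n} exceeds vocabulary size {len(model.dictionary)}")
    row = model.phi[topic_id]
    ids = _top_word_ids(row, n)
    return [(model.dictionary.words[i], float(row[i])) for i in ids]


def topic_overlap(model: TopicModelResult, top_n: int = 10) -> float:
    """Mean pairwise |top_n(i) ∩ top_n(j)| / top_n over unordered topic pairs."""
    if model.K < 2:
        raise ValueError("topic_overlap requires K >= 2")
    if top_n > len(model.dictionary):
        raise ValueError(f"top_n={top_n} exceeds vocabulary size {len(model.dictionary)}")
    tops = [set(_top_word_ids(model.phi[t], top_n).tolist()) for t in range(model.K)]
    sims = [len(a & b) / top_n for a, b in itertools.combinations(tops, 2)]
    return float(np.mean(sims))


def dominant_topic(theta_row: np.ndarray) -> tuple[int, float]:
    """Argmax of a document's topic distribution; ties break to the lowest id."""
    theta_row = np.asarray(theta_row, dtype=float)
    if theta_row.size == 0:
        raise ValueError("empty topic distribution")
    idx = int(np.argmax(theta_row))  # np.argmax returns the first maximum
    return idx, float(theta_row[idx])


# ---------------------------------------------------------------------------
# coherence


class CoherenceScorer:
    """Sliding-window NPMI coherence over a tokenized corpus.

    Counts word and word-pair occurrences in overlapping windows of
    ``window_size`` tokens (one boolean occurrence per window), then scores a
    topic as the mean NPMI of its top-word pairs and a model as the mean over
    topics.  ``measure="umass"`` instead uses document co-occurrence with the
    classic asymmetric log-ratio.
    """

    def __init__(
        self,
        corpus: Sequence[TokenizedDocument],
        measure: str = "npmi",
        window_size: int = 10,
    ):
        if measure not in ("npmi", "umass"):
            raise ValueError(f"unknown coherence measure {measure!r}")
        self.measure = measure
        self.window_size = window_size
        self._corpus = corpus
        self._n_windows = 0
        self._occ: dict[str, int] = {}
        self._cooc: dict[tuple[str, str], int] = {}
        self._counted_vocab: set[str] = set()

    def _ensure_counts(self, vocab: set[str]) -> None:
        missing = vocab - self._counted_vocab
        if not missing:
            return
        # recount from scratch over the union (simple and deterministic; the
        # candidate vocabulary across a K-range scan is small)
        self._counted_vocab |= missing
        vocab = self._counted_vocab
        occ: dict[str, int] = {}
        cooc: dict[tuple[str, str], int] = {}
        n_windows = 0
        for doc in self._corpus:
            toks = doc.tokens
            if self.measure == "umass":
                spans = [toks]  # whole document as one window
            else:
                size = self.window_size
                if len(toks) <= size:
                    spans = [toks]
                else:
                    spans = [toks[i : i + size] for i in range(len(toks) - size + 1)]
            for span in spans:
                present = sorted(vocab.intersection(span))
                if not present:
                    n_windows += 1
                    continue
                for w in present:
                    occ[w] = occ.get(w, 0) + 1
                for a, b in itertools.combinations(present, 2):
                    cooc[(a, b)] = cooc.get((a, b), 0) + 1
                n_windows += 1
        self._occ, self._cooc, self._n_windows = occ, cooc, n_windows

    def _pair_count(self, a: str, b: str) -> int:
        key = (a, b) if a <= b else (b, a)
        return self._cooc.get(key, 0)

    def topic_score(self, top_words: Sequence[str]) -> float:
        self._ensure_counts(set(top_words))
        n = self._n_windows
        eps = 1e-12
        scores = []
        for a, b in itertools.combinations(top_words, 2):
            ca, cb, cab = self._occ.get(a, 0), self._occ.get(b, 0), self._pair_count(a, b)
            if self.measure == "umass":
                if ca and cb:
                    # asymmetric: condition on the more frequent word
                    hi, lo = (a, b) if ca >= cb else (b, a)
                    scores.append(np.log((self._pair_count(hi, lo) + 1) / self._occ[lo]))
                continue
            if ca == 0 or cb == 0:
                scores.append(-1.0)
                continue
            p_a, p_b, p_ab = ca / n, cb / n, cab / n
            if p_ab <= 0:
                scores.append(-1.0)
                continue
            pmi = np.log(p_ab / (p_a * p_b) + eps)
            scores.append(float(pmi / -np.log(p_ab + eps)))
        return float(np.mean(scores)) if scores else 0.0

    def model_score(self, model: TopicModelResult, top_n: int = 10) -> float:
        return float(
            np.mean([self.topic_score([w for w, _ in top_keywords(model, t, top_n)])
                     for t in range(model.K)])
        )


# ---------------------------------------------------------------------------
# model selection


def select_k_rule(rows: list[dict]) -> tuple[int, str]:
    """Default automatic selection: among candidates whose topic overlap is at
    or below the median overlap across the range, choose the K with maximal
    coherence (ties toward smaller K).

    This mirrors manual selection from the three curves: overlap gates out
    redundant-topic models, coherence then picks the most interpretable one.
    """
    valid = [r for r in rows if not r.get("error")]
    if not valid:
        raise ValueError("no successfully trained candidate K")
    med = float(np.median([r["topic_overlap"] for r in valid]))
    pool = [r for r in valid if r["topic_overlap"] <= med] or valid
    best = max(pool, key=lambda r: (r["coherence"], -r["K"]))
    return int(best["K"]), "overlap<=median then max coherence"


def evaluate_topic_range(
    bow: Sequence[BowDocument],
    dictionary: FilteredDictionary,
    corpus: Sequence[TokenizedDocument],
    K_range: Sequence[int] = range(2, 20),
    seed: int = 0,
    passes: int = 20,
    coherence_measure: str = "npmi",
    coherence_window: int = 10,
    top_n: int = 10,
    forced_k: int | None = None,
) -> ModelSelectionReport:
    """Train and score one LDA model per candidate K.

    Each row records coherence, per-word log-likelihood bound, and topic
    overlap; per-K failures annotate the row rather than aborting the scan.
    ``forced_k`` overrides the automatic rule (manual selection).
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    scorer = CoherenceScorer(corpus, measure=coherence_measure, window_size=coherence_window)
    rows: list[dict] = []
    for K in K_range:
        row: dict = {"K": K, "coherence": np.nan, "log_perplexity": np.nan,
                     "topic_overlap": np.nan, "error": ""}
        try:
            model = train_lda(bow, dictionary, K, seed=stable_seed(seed, f"lda-K{K}"), passes=passes)
            eff_top_n = min(top_n, len(dictionary))
            row["coherence"] = scorer.model_score(model, eff_top_n)
            row["log_perplexity"] = model.log_perplexity
            row["topic_overlap"] = topic_overlap(model, eff_top_n)
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    if forced_k is not None:
        if forced_k not in K_range:
            raise ValueError(f"forced K={forced_k} not among candidates {K_range}")
        chosen, rule = forced_k, "forced"
    else:
        chosen, rule = select_k_rule(rows)
    return ModelSelectionReport(rows=rows, chosen_K=chosen, selection_rule=rule)


# ---------------------------------------------------------------------------
# persistence


def save_dictionary(dictionary: FilteredDictionary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "words": list(dictionary.words),
                "doc_freq": list(dictionary.doc_freq),
                "n_docs": dictionary.n_docs,
                "min_doc_count": dictionary.min_doc_count,
                "max_doc_fraction": dictionary.max_doc_fraction,
            },
            fh,
        )


def load_dictionary(path: str | Path) -> FilteredDictionary:
    obj = json.loads(Path(path).read_text())
    return FilteredDictionary(
        tuple(obj["words"]), tuple(obj["doc_freq"]), obj["n_docs"],
        obj["min_doc_count"], obj["max_doc_fraction"],
    )


def save_selection_report(report: ModelSelectionReport, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["K", "coherence", "log_perplexity", "topic_overlap", "error"])
        for r in report.rows:
            writer.writerow([r["K"], r["coherence"], r["log_perplexity"], r["topic_overlap"], r["error"]])


def save_topic_table(model: TopicModelResult, path: str | Path, n: int = 10) -> None:
    """Topic table: one row per topic with its top words and probabilities."""
    n = min(n, len(model.dictionary))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic_id", "rank", "word", "probability"])
        for t in range(model.K):
            for rank, (w, p) in enumerate(top_keywords(model, t, n)):
                writer.writerow([t, rank, w, f"{p:.8f}"])


def save_dominant_topic_counts(model: TopicModelResult, path: str | Path) -> None:
    counts = np.zeros(model.K, dtype=int)
    for row in model.theta:
        counts[dominant_topic(row)[0]] += 1
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["topic_id", "n_documents"])
        for t, c in enumerate(counts):
            writer.writerow([t, int(c)])
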