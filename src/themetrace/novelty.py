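"""Recency-based novelty indicators and temporal backtesting.

Cluster Novelty N_C is the mean publication year of a cluster's documents;
Topic Novelty N_{c,t} is the mean year over the cluster-c documents that
*include* topic t (by default: t is among the document's top-5 topics by
theta, matching the document-vector construction).  Both are plain calendar
means — novelty measures recency of activity, not volume.

Forecasting: the dominant topics of clusters whose N_C exceeds the phase
mean form the predicted "novel" topic set; backtesting compares that set
against the dominant topics actually observed in the next phase, scoring
precision and recall.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clustering import ClusterProfile, PhaseClustering
from .errors import ConfigurationError
from .topic_model import TopicModelResult

_STRATEGIES = ("above_mean", "top_m", "year_threshold")
_INCLUSION_RULES = ("top5", "threshold")


@dataclass(frozen=True)
class ClusterNovelty:
    phase: str
    cluster_id: int
    score: float        # year scale
    n_members: int
    dominant_topic: int


@dataclass(frozen=True)
class TopicNoveltyCell:
    phase: str
    cluster_id: int
    topic_id: int
    score: float | None  # None when no member includes the topic
    n_members: int       # members that include the topic
    weight_share: float  # cluster mean theta for the topic


@dataclass(frozen=True)
class BacktestResult:
    train_phase: str
    test_phase: str
    predicted_topics: frozenset[int]
    actual_topics: frozenset[int]
    precision: float | None  # None when the predicted set is empty
    recall: float | None     # None when the actual set is empty
    strategy: str


def cluster_novelty(member_years: Sequence[int]) -> float:
    """Arithmetic mean publication year of the cluster's documents."""
    if len(member_years) == 0:
        raise ValueError("cluster has no members")
    return float(np.mean(member_years))


def _includes_topic(theta_row: np.ndarray, topic: int, rule: str, top_m: int, threshold: float) -> bool:
    if rule == "top5":
        order = np.lexsort((np.arange(theta_row.size), -theta_row))[: min(top_m, theta_row.size)]
        return topic in order
    if rule == "threshold":
        return theta_row[topic] >= threshold
    raise ConfigurationError(f"unknown inclusion rule {rule!r}; valid: {', '.join(_INCLUSION_RULES)}")


def topic_novelty(
    members: Sequence[tuple[str, int, np.ndarray]],
    topic: int,
    phase: str = "",
    cluster_id: int = 0,
    inclusion_rule: str = "top5",
    top_m: int = 5,
    theta_threshold: float = 0.1,
) -> TopicNoveltyCell:
    """Mean year over the members that include the topic.

    ``members`` is a list of (doc_id, year, theta_row).  A cell with no
    qualifying member is undefined (score None, n 0) — a value, not an error.
    """
    if not members:
        raise ValueError("cluster has no members")
    years = [
        year for _, year, theta in members
        if _includes_topic(np.asarray(theta, dtype=float), topic, inclusion_rule, top_m, theta_threshold)
    ]
    share = float(np.mean([np.asarray(t, dtype=float)[topic] for _, _, t in members]))
    score = float(np.mean(years)) if years else None
    return TopicNoveltyCell(phase, cluster_id, topic, score, len(years), share)


def phase_cluster_novelty(
    pc: PhaseClustering,
    profiles: Sequence[ClusterProfile],
    years_by_doc: Mapping[str, int],
) -> list[ClusterNovelty]:
    out = []
    for prof in sorted(profiles, key=lambda p: p.cluster_id):
        years = [years_by_doc[pc.doc_ids[i]] for i in pc.members(prof.cluster_id)]
        out.append(
            ClusterNovelty(pc.phase, prof.cluster_id, cluster_novelty(years), len(years),
                           prof.dominant_topic[0])
        )
    return out


def phase_topic_novelty(
    pc: PhaseClustering,
    model: TopicModelResult,
    years_by_doc: Mapping[str, int],
    inclusion_rule: str = "top5",
    top_m: int = 5,
    theta_threshold: float = 0.1,
) -> list[TopicNoveltyCell]:
    cells = []
    for c in range(pc.k):
        members = [
            (pc.doc_ids[i], years_by_doc[pc.doc_ids[i]], model.theta_for(pc.doc_ids[i]))
            for i in pc.members(c)
        ]
        for t in range(model.K):
            cells.append(
                topic_novelty(members, t, pc.phase, c, inclusion_rule, top_m, theta_threshold)
            )
    return cells


def predict_novel_topics(
    novelties: Sequence[ClusterNovelty],
    strategy: str = "above_mean",
    top_m: int = 2,
    year_threshold: float | None = None,
) -> frozenset[int]:
    """Predicted novel-topic set for a phase.

    - ``above_mean`` (default): dominant topics of clusters whose N_C
      strictly exceeds the unweighted mean of the phase's scores.
    - ``top_m``: dominant topics of the ``top_m`` highest-novelty clusters.
    - ``year_threshold``: dominant topics of clusters with N_C >= threshold.
    """
    if strategy not in _STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}; valid: {', '.join(_STRATEGIES)}")
    if not novelties:
        return frozenset()
    if strategy == "above_mean":
        mean = float(np.mean([n.score for n in novelties]))
        picked = [n for n in novelties if n.score > mean]
    elif strategy == "top_m":
        picked = sorted(novelties, key=lambda n: (-n.score, n.cluster_id))[:top_m]
    else:
        if year_threshold is None:
            raise ConfigurationError("year_threshold strategy requires a threshold")
        picked = [n for n in novelties if n.score >= year_threshold]
    return frozenset(n.dominant_topic for n in picked)


def backtest(
    train_novelties: Sequence[ClusterNovelty],
    test_profiles: Sequence[ClusterProfile],
    phase_order: Sequence[str],
    strategy: str = "above_mean",
    top_m: int = 2,
    year_threshold: float | None = None,
) -> BacktestResult:
    """Score the train phase's predicted topics against the test phase.

    actual = dominant topics over the test phase's clusters;
    precision = |pred ∩ actual| / |pred| (undefined for an empty prediction);
    recall = |pred ∩ actual| / |actual| (0 when actual is non-empty and the
    prediction is empty; undefined when actual is empty).  The phases must be
    consecutive.
    """
    if not train_novelties or not test_profiles:
        raise ValueError("both phases must be clustered and profiled")
    train_phase = train_novelties[0].phase
    test_phase = test_profiles[0].phase
    order = list(phase_order)
    if train_phase not in order or test_phase not in order:
        raise ConfigurationError("phases not found in phase order")
    if order.index(test_phase) != order.index(train_phase) + 1:
        raise ConfigurationError(
            f"backtest requires consecutive phases, got {train_phase!r} -> {test_phase!r}"
        )
    predicted = predict_novel_topics(train_novelties, strategy, top_m, year_threshold)
    actual = frozenset(p.dominant_topic[0] for p in test_profiles)
    hit = len(predicted & actual)
    precision = hit / len(predicted) if predicted else None
    recall = hit / len(actual) if actual else None
    return BacktestResult(train_phase, test_phase, predicted, actual, precision, recall, strategy)


def sunburst_table(
    profiles: Sequence[ClusterProfile],
    cells: Sequence[TopicNoveltyCell],
) -> list[dict]:
    """One row per defined (cluster, topic) cell: weight share and mean year.

    The inner ring of the corresponding figure is the clusters, the outer
    ring the topics; undefined cells (no qualifying member) are omitted.
    """
    rows = []
    for cell in cells:
        if cell.score is None:
            continue
        rows.append(
            {
                "phase": cell.phase,
                "cluster_id": cell.cluster_id,
                "topic_id": cell.topic_id,
                "weight_share": cell.weight_share,
                "avg_year": cell.score,
                "n_documents": cell.n_members,
            }
        )
    rows.sort(key=lambda r: (r["phase"], r["cluster_id"], r["topic_id"]))
    return rows


# ---------------------------------------------------------------------------
# persistence


def write_cluster_novelty_csv(novelties: Sequence[ClusterNovelty], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cluster_label", "avg_year", "n_documents", "dominant_topic"])
        for n in sorted(novelties, key=lambda n: (n.phase, -n.score, n.cluster_id)):
            writer.writerow([f"{n.phase}_C{n.cluster_id}", f"{n.score:.3f}", n.n_members,
                             f"Topic_{n.dominant_topic}"])


def write_sunburst_csv(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phase", "cluster_id", "topic_id", "weight_share", "avg_year", "n_documents"])
        for r in rows:
            writer.writerow(
                [r["phase"], r["cluster_id"], r["topic_id"],
                 f"{r['weight_share']:.6f}", f"{r['avg_year']:.3f}", r["n_documents"]]
            )


def write_backtest_csv(results: Sequence[BacktestResult], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["train_period", "test_period", "precision", "recall", "strategy",
                         "predicted_topics", "actual_topics"])
        for r in results:
            writer.writerow(
                [r.train_phase, r.test_phase,
                 "" if r.precision is None else f"{r.precision:.3f}",
                 "" if r.recall is None else f"{r.recall:.3f}",
                 r.strategy,
                 " ".join(str(t) for t in sorted(r.predicted_topics)),
                 " ".join(str(t) for t in sorted(r.actual_topics))]
            )
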