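"""Cross-phase cluster linking by centroid cosine similarity.

Clusters of adjacent phases are compared through the cosine similarity of
their raw-space centroids (per-phase z-scores are not comparable across
phases).  Pairs at or above the threshold (default 0.8) become evolution
links; the retained links plus all cluster nodes form the Sankey structure,
a layered graph in which links connect only adjacent phases.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clustering import ClusterProfile, PhaseClustering
from .errors import StructureError

DEFAULT_THRESHOLD = 0.8


@dataclass(frozen=True)
class EvolutionLink:
    source_phase: str
    source_cluster: int
    source_topic: int
    target_phase: str
    target_cluster: int
    target_topic: int
    similarity: float


@dataclass(frozen=True)
class SankeyNode:
    phase: str
    cluster_id: int
    label: str
    size: int
    dominant_topic: int


@dataclass
class SankeyStructure:
    nodes: list[SankeyNode]
    links: list[EvolutionLink]


def centroid_similarity(prev: PhaseClustering, next: PhaseClustering) -> np.ndarray:
    """Cosine matrix between raw-space centroids of two adjacent phases.

    Entry (i, j) is the cosine of prev centroid i with next centroid j.
    Zero-norm centroids yield NaN entries with a warning.
    """
    A, B = prev.centroids_raw, next.centroids_raw
    if A.shape[1] != B.shape[1]:
        raise ValueError("centroid dimensions differ between phases")
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if (na == 0).any() or (nb == 0).any():
        warnings.warn("zero-norm centroid: affected similarities recorded as NaN", stacklevel=2)
    sim = A @ B.T / np.outer(np.where(na == 0, np.nan, na), np.where(nb == 0, np.nan, nb))
    return sim


def filter_links(
    similarity: np.ndarray,
    prev_profiles: Sequence[ClusterProfile],
    next_profiles: Sequence[ClusterProfile],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[EvolutionLink]:
    """Retain cluster pairs with similarity >= threshold (inclusive).

    Many-to-many links are allowed; NaN entries (zero-norm centroids) are
    never retained.  Links carry the dominant topics from the profiles.
    """
    prev_by_id = {p.cluster_id: p for p in prev_profiles}
    next_by_id = {p.cluster_id: p for p in next_profiles}
    links = []
    for i in range(similarity.shape[0]):
        for j in range(similarity.shape[1]):
            s = similarity[i, j]
            if np.isnan(s) or s < threshold:
                continue
            sp, tp = prev_by_id[i], next_by_id[j]
            links.append(
                EvolutionLink(
                    source_phase=sp.phase, source_cluster=i, source_topic=sp.dominant_topic[0],
                    target_phase=tp.phase, target_cluster=j, target_topic=tp.dominant_topic[0],
                    similarity=float(s),
                )
            )
    return links


def link_phases(
    clusterings: Sequence[PhaseClustering],
    profiles_by_phase: Mapping[str, Sequence[ClusterProfile]],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[EvolutionLink]:
    """Links across every adjacent pair in chronological order."""
    links: list[EvolutionLink] = []
    for prev, nxt in zip(clusterings, clusterings[1:]):
        sim = centroid_similarity(prev, nxt)
        links.extend(
            filter_links(sim, profiles_by_phase[prev.phase], profiles_by_phase[nxt.phase], threshold)
        )
    return links


def build_sankey(
    profiles_by_phase: Mapping[str, Sequence[ClusterProfile]],
    links: Sequence[EvolutionLink],
    phase_order: Sequence[str],
) -> SankeyStructure:
    """Assemble nodes (ordered by phase then cluster id) and retained links.

    A link endpoint that names no existing node is a structural error.
    """
    nodes = []
    node_keys = set()
    for phase in phase_order:
        for prof in sorted(profiles_by_phase.get(phase, []), key=lambda p: p.cluster_id):
            nodes.append(
                SankeyNode(
                    phase=phase,
                    cluster_id=prof.cluster_id,
                    label=f"{phase}_C{prof.cluster_id}",
                    size=prof.size,
                    dominant_topic=prof.dominant_topic[0],
                )
            )
            node_keys.add((phase, prof.cluster_id))
    for link in links:
        for end in ((link.source_phase, link.source_cluster), (link.target_phase, link.target_cluster)):
            if end not in node_keys:
                raise StructureError(f"dangling link endpoint {end}")
    return SankeyStructure(nodes=nodes, links=list(links))


def write_links_csv(links: Sequence[EvolutionLink], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["source_phase", "source_cluster", "source_topic",
             "target_phase", "target_cluster", "target_topic", "similarity"]
        )
        for l in links:
            writer.writerow(
                [l.source_phase, l.source_cluster, l.source_topic,
                 l.target_phase, l.target_cluster, l.target_topic, f"{l.similarity:.6f}"]
            )


def write_nodes_csv(sankey: SankeyStructure, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["phase", "cluster_id", "label", "size", "dominant_topic"])
        for n in sankey.nodes:
            writer.writerow([n.phase, n.cluster_id, n.label, n.size, n.dominant_topic])
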