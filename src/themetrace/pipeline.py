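"""End-to-end orchestration: corpus → embeddings → topics → fusion →
per-phase clustering → evolution links → novelty and backtests.

Every stage persists its artifacts as plain CSV/JSON under the output
directory and registers them in ``manifest.csv`` (file, stage, sha256).
One global seed deterministically derives per-stage seeds, so a fixed
configuration reproduces byte-identical artifacts.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering as tc
from . import corpus_io, embedding as emb, evolution as evo, fusion, novelty as nov
from . import synthetic, topic_model as tm
from .config import PipelineConfig, save_config
from .errors import ThemetraceError
from .fingerprint import file_sha256, stable_seed

logger = logging.getLogger(__name__)

STAGES = ("ingest", "embed", "topics", "fuse", "cluster", "evolve", "novelty")


@dataclass
class PipelineState:
    """In-memory results accumulated while stages run."""

    config: PipelineConfig
    records: list = field(default_factory=list)
    exclusions: dict = field(default_factory=dict)
    docs: list = field(default_factory=list)
    flagged: list = field(default_factory=list)
    embedding_model: emb.EmbeddingModel | None = None
    grid_report: emb.GridSearchReport | None = None
    dictionary: tm.FilteredDictionary | None = None
    bow: list = field(default_factory=list)
    selection: tm.ModelSelectionReport | None = None
    model: tm.TopicModelResult | None = None
    doc_vectors: list = field(default_factory=list)
    topic_vectors: list = field(default_factory=list)
    clusterings: list = field(default_factory=list)
    profiles_by_phase: dict = field(default_factory=dict)
    links: list = field(default_factory=list)
    sankey: evo.SankeyStructure | None = None
    manifest: list = field(default_factory=list)  # (file, stage)

    @property
    def years_by_doc(self) -> dict[str, int]:
        return {d.doc_id: d.year for d in self.docs}


def _register(state: PipelineState, stage: str, path: Path) -> None:
    state.manifest.append((path, stage))


def _load_records(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    fmt = cfg.input.format
    if fmt.startswith("preset:"):
        parts = fmt.split(":")  # preset:<name>[:n_docs]
        name = parts[1]
        n_docs = int(parts[2]) if len(parts) > 2 else None
        spec = synthetic.preset_scenario(name, seed=stable_seed(cfg.seed, "simulate"), n_docs=n_docs)
        records, truth = synthetic.generate_corpus(spec)
        corpus_path = out / "synthetic_corpus.csv"
        synthetic.write_corpus_csv(records, corpus_path)
        synthetic.write_ground_truth(truth, out / "truth")
        _register(state, "ingest", corpus_path)
        _register(state, "ingest", out / "truth" / "ground_truth.csv")
        _register(state, "ingest", out / "truth" / "signatures.json")
        state.records, state.exclusions = corpus_io.read_corpus(corpus_path, format="csv")
    else:
        state.records, state.exclusions = corpus_io.read_corpus(
            cfg.input.path, format=fmt, column_map=cfg.input.columns or None
        )


def run_pipeline(cfg: PipelineConfig, through: str = "novelty") -> list[dict]:
    """Run the pipeline from ingest through ``through`` (inclusive).

    Returns the manifest: one entry per artifact with its stage and content
    hash.  A stage failure aborts with the stage name; artifacts completed
    before the failure remain on disk.
    """
    if through not in STAGES:
        raise ThemetraceError(f"unknown stage {through!r}; stages: {', '.join(STAGES)}")
    last = STAGES.index(through)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState(config=cfg)
    save_config(cfg, out / "effective_config.yml")
    _register(state, "config", out / "effective_config.yml")

    try:
        for stage in STAGES[: last + 1]:
            logger.info("stage %s: start", stage)
            _STAGE_FNS[stage](cfg, out, state)
            logger.info("stage %s: done", stage)
    except Exception as exc:
        _write_manifest(state, out)
        raise ThemetraceError(f"pipeline failed in stage: {exc}") from exc
    return _write_manifest(state, out)


def _stage_ingest(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    _load_records(cfg, out, state)
    stopwords = corpus_io.load_stopwords(cfg.stopword_file)
    state.docs, state.flagged = corpus_io.preprocess_corpus(
        state.records, stopwords, keep_numbers=cfg.keep_numbers, min_tokens=cfg.min_tokens
    )
    if not state.docs:
        raise corpus_io.EmptyCorpusError("no documents survived preprocessing")
    tokens_path = out / "tokens.jsonl"
    corpus_io.write_tokens_jsonl(state.docs, tokens_path)
    report = dict(state.exclusions)
    report["below_min_tokens"] = len(state.flagged)
    excl_path = out / "exclusions.csv"
    corpus_io.write_exclusion_report(report, excl_path)
    _register(state, "ingest", tokens_path)
    _register(state, "ingest", excl_path)


def _load_pairs(cfg: PipelineConfig) -> emb.CoherencePairSet:
    if cfg.embedding.pairs_file:
        pairs = []
        with open(cfg.embedding.pairs_file, encoding="utf-8") as fh:
            for line in fh:
                parts = line.split()
                if len(parts) == 2:
                    pairs.append((parts[0].lower(), parts[1].lower()))
        return emb.CoherencePairSet(tuple(pairs))
    return emb.default_pair_set()


def _corpus_pairs(docs: Sequence[corpus_io.TokenizedDocument], seed: int) -> emb.CoherencePairSet:
    """Fallback coherence pairs sampled from within-document co-occurrence.

    Used when the user supplies no pair file and the default domain pairs do
    not cover the corpus vocabulary (e.g. synthetic corpora): the most
    frequent within-document co-occurring word pairs are taken as
    semantically related.
    """
    from collections import Counter

    counts: Counter = Counter()
    rng = np.random.default_rng(seed)
    for doc in docs:
        toks = list(dict.fromkeys(doc.tokens))[:50]
        if len(toks) < 2:
            continue
        idx = rng.choice(len(toks), size=(min(10, len(toks) // 2), 2))
        for a, b in idx:
            if toks[a] != toks[b]:
                counts[tuple(sorted((toks[a], toks[b])))] += 1
    top = [p for p, _ in counts.most_common(20)]
    return emb.CoherencePairSet(tuple(top))


def _stage_embed(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    opts = emb.TrainingOptions(
        epochs=cfg.embedding.epochs,
        min_count=cfg.embedding.min_count,
        negative=cfg.embedding.negative,
    )
    pairs = _load_pairs(cfg)
    vocab = {t for d in state.docs for t in d.tokens}
    covered = sum(1 for p in pairs.pairs if p[0] in vocab and p[1] in vocab)
    if covered == 0:
        logger.warning("no default coherence pair covers the corpus; sampling corpus pairs")
        pairs = _corpus_pairs(state.docs, stable_seed(cfg.seed, "pairs"))
    seed = stable_seed(cfg.seed, "embed")
    report = emb.grid_search(
        state.docs, cfg.embedding.dims, cfg.embedding.windows, pairs, seed=seed, opts=opts
    )
    state.grid_report = report
    dim, window = report.best_config
    state.embedding_model = emb.train_embedding(state.docs, dim, window, seed=seed, opts=opts)

    grid_path = out / "embedding_grid.csv"
    pd.DataFrame(report.rows).to_csv(grid_path, index=False)
    vec_path = out / "embedding.vec"
    emb.save_word2vec_format(state.embedding_model, vec_path)
    for p in (grid_path, vec_path, vec_path.with_suffix(".vec.meta.json")):
        _register(state, "embed", p)


def _stage_topics(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    state.dictionary = tm.build_dictionary(state.docs)
    state.bow, dropped = tm.to_bow(state.docs, state.dictionary)
    k_range = range(cfg.lda.k_min, cfg.lda.k_max + 1)
    seed = stable_seed(cfg.seed, "topics")
    state.selection = tm.evaluate_topic_range(
        state.bow, state.dictionary, state.docs,
        K_range=k_range, seed=seed, passes=cfg.lda.passes,
        coherence_measure=cfg.lda.coherence_measure,
        coherence_window=cfg.lda.coherence_window,
        forced_k=cfg.lda.chosen_k,
    )
    K = state.selection.chosen_K
    state.model = tm.train_lda(
        state.bow, state.dictionary, K, seed=stable_seed(seed, f"lda-K{K}"), passes=cfg.lda.passes
    )

    paths = {
        "dictionary.json": lambda p: tm.save_dictionary(state.dictionary, p),
        "selection_report.csv": lambda p: tm.save_selection_report(state.selection, p),
        "topic_keywords.csv": lambda p: tm.save_topic_table(state.model, p),
        "dominant_topic_counts.csv": lambda p: tm.save_dominant_topic_counts(state.model, p),
    }
    for name, writer in paths.items():
        path = out / name
        writer(path)
        _register(state, "topics", path)
    with open(out / "bow_dropped.json", "w") as fh:
        json.dump({"dropped_doc_ids": dropped, "count": len(dropped)}, fh)
    _register(state, "topics", out / "bow_dropped.json")


def _stage_fuse(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    state.doc_vectors, state.topic_vectors = fusion.fuse_corpus(
        state.model, state.embedding_model, top_n=cfg.fusion.top_n, top_m=cfg.fusion.top_m
    )
    years = state.years_by_doc
    rows = []
    for dv in state.doc_vectors:
        row = {"doc_id": dv.doc_id, "year": years[dv.doc_id]}
        row.update({f"v{i}": float(x) for i, x in enumerate(dv.vector)})
        rows.append(row)
    dv_path = out / "doc_vectors.csv"
    pd.DataFrame(rows).to_csv(dv_path, index=False, float_format="%.10g")
    tv_rows = []
    for tv in state.topic_vectors:
        row = {"topic_id": tv.topic_id,
               "used_keywords": " ".join(w for w, _ in tv.used_keywords),
               "dropped_keywords": " ".join(tv.dropped_keywords)}
        row.update({f"v{i}": float(x) for i, x in enumerate(tv.vector)})
        tv_rows.append(row)
    tv_path = out / "topic_vectors.csv"
    pd.DataFrame(tv_rows).to_csv(tv_path, index=False, float_format="%.10g")
    _register(state, "fuse", dv_path)
    _register(state, "fuse", tv_path)


def _stage_cluster(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    by_id = {dv.doc_id: dv for dv in state.doc_vectors}
    segmented = corpus_io.segment_by_phase(
        [d for d in state.docs if d.doc_id in by_id], cfg.phases
    )
    k_range = range(cfg.clustering.k_min, cfg.clustering.k_max + 1)
    state.clusterings = []
    state.profiles_by_phase = {}
    assign_rows, sil_rows, prof_rows, matrix_rows = [], [], [], []
    for phase in cfg.phases:
        docs = segmented[phase.label]
        if not docs:
            logger.warning("phase %s is empty; skipped", phase.label)
            continue
        vectors = [by_id[d.doc_id] for d in docs]
        pc = tc.cluster_phase_auto(
            vectors, phase=phase.label, k_range=k_range,
            seed=stable_seed(cfg.seed, f"cluster-{phase.label}"),
            n_init=cfg.clustering.n_init,
            min_phase_size=cfg.clustering.min_phase_size,
        )
        profiles = tc.profile_phase(pc, state.model)
        state.clusterings.append(pc)
        state.profiles_by_phase[phase.label] = profiles
        for doc_id, c in pc.assignments.items():
            assign_rows.append({"doc_id": doc_id, "phase": phase.label, "cluster": c})
        for k, s in sorted(pc.silhouette_by_k.items()):
            sil_rows.append({"phase": phase.label, "k": k, "silhouette": s})
        for p in profiles:
            prof_rows.append(
                {
                    "phase": p.phase, "cluster": p.cluster_id, "size": p.size,
                    "dominant_topic": p.dominant_topic[0],
                    "dominant_weight": p.dominant_topic[1],
                    "representative_doc": p.representative_doc,
                    "top_keywords": " ".join(w for w, _ in p.keywords),
                }
            )
            row = {"phase": p.phase, "cluster": p.cluster_id}
            row.update({f"topic_{t}": float(w) for t, w in enumerate(p.mean_topic_weights)})
            matrix_rows.append(row)
    outputs = {
        "assignments.csv": assign_rows,
        "silhouette.csv": sil_rows,
        "cluster_profiles.csv": prof_rows,
        "cluster_topic_matrix.csv": matrix_rows,
    }
    for name, rows in outputs.items():
        path = out / name
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
        _register(state, "cluster", path)


def _stage_evolve(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    state.links = evo.link_phases(
        state.clusterings, state.profiles_by_phase, threshold=cfg.evolution.threshold
    )
    phase_order = [pc.phase for pc in state.clusterings]
    state.sankey = evo.build_sankey(state.profiles_by_phase, state.links, phase_order)
    links_path = out / "evolution_links.csv"
    nodes_path = out / "sankey_nodes.csv"
    evo.write_links_csv(state.links, links_path)
    evo.write_nodes_csv(state.sankey, nodes_path)
    _register(state, "evolve", links_path)
    _register(state, "evolve", nodes_path)


def _stage_novelty(cfg: PipelineConfig, out: Path, state: PipelineState) -> None:
    years = state.years_by_doc
    all_novelties: dict[str, list[nov.ClusterNovelty]] = {}
    all_cells: list[nov.TopicNoveltyCell] = []
    for pc in state.clusterings:
        profiles = state.profiles_by_phase[pc.phase]
        all_novelties[pc.phase] = nov.phase_cluster_novelty(pc, profiles, years)
        all_cells.extend(
            nov.phase_topic_novelty(
                pc, state.model, years,
                inclusion_rule=cfg.novelty.inclusion_rule,
                top_m=cfg.fusion.top_m,
            )
        )
    flat = [n for ns in all_novelties.values() for n in ns]
    nov.write_cluster_novelty_csv(flat, out / "cluster_novelty.csv")
    profiles_flat = [p for ps in state.profiles_by_phase.values() for p in ps]
    nov.write_sunburst_csv(nov.sunburst_table(profiles_flat, all_cells), out / "topic_novelty.csv")

    phase_order = [pc.phase for pc in state.clusterings]
    predictions = {
        phase: sorted(
            nov.predict_novel_topics(
                ns, cfg.novelty.strategy, cfg.novelty.top_m, cfg.novelty.year_threshold
            )
        )
        for phase, ns in all_novelties.items()
    }
    with open(out / "predicted_topics.json", "w") as fh:
        json.dump({"strategy": cfg.novelty.strategy, "predicted": predictions}, fh, indent=2)

    results = []
    for train, test in zip(phase_order, phase_order[1:]):
        results.append(
            nov.backtest(
                all_novelties[train], state.profiles_by_phase[test], phase_order,
                strategy=cfg.novelty.strategy, top_m=cfg.novelty.top_m,
                year_threshold=cfg.novelty.year_threshold,
            )
        )
    nov.write_backtest_csv(results, out / "backtest.csv")
    for name in ("cluster_novelty.csv", "topic_novelty.csv", "predicted_topics.json", "backtest.csv"):
        _register(state, "novelty", out / name)


_STAGE_FNS = {
    "ingest": _stage_ingest,
    "embed": _stage_embed,
    "topics": _stage_topics,
    "fuse": _stage_fuse,
    "cluster": _stage_cluster,
    "evolve": _stage_evolve,
    "novelty": _stage_novelty,
}


def _write_manifest(state: PipelineState, out: Path) -> list[dict]:
    entries = []
    for path, stage in state.manifest:
        if Path(path).exists():
            entries.append(
                {"file": str(Path(path).relative_to(out)), "stage": stage,
                 "sha256": file_sha256(path)}
            )
    with open(out / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "stage", "sha256"])
        for e in entries:
            writer.writerow([e["file"], e["stage"], e["sha256"]])
    return entries
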