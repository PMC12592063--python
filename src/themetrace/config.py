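"""Declarative pipeline configuration (YAML) with strict validation.

Unknown keys are hard errors (typo guard); every default that gets filled in
is logged.  ``validate → serialize → validate`` round-trips to an identical
effective configuration.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .corpus_io import DEFAULT_PHASES, PhaseDefinition, validate_phases
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InputConfig:
    path: str = ""
    format: str = "csv"          # csv | wos_tab | preset:<name>
    columns: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EmbeddingConfig:
    dims: tuple[int, ...] = (50, 100, 200, 300)
    windows: tuple[int, ...] = (2, 5, 10)
    pairs_file: str | None = None
    epochs: int = 50
    min_count: int = 2
    negative: int = 5


@dataclass(frozen=True)
class LdaConfig:
    k_min: int = 2
    k_max: int = 19
    passes: int = 20
    chosen_k: int | None = None          # manual override of the selection rule
    coherence_measure: str = "npmi"
    coherence_window: int = 10


@dataclass(frozen=True)
class FusionConfig:
    top_n: int = 10   # keywords per topic vector
    top_m: int = 5    # topics per document vector


@dataclass(frozen=True)
class ClusteringConfig:
    k_min: int = 2
    k_max: int = 10
    n_init: int = 10
    min_phase_size: int = 10


@dataclass(frozen=True)
class EvolutionConfig:
    threshold: float = 0.8
    space: str = "raw"   # raw | standardized centroids for cross-phase cosine


@dataclass(frozen=True)
class NoveltyConfig:
    strategy: str = "above_mean"
    inclusion_rule: str = "top5"
    top_m: int = 2
    year_threshold: float | None = None


@dataclass(frozen=True)
class PipelineConfig:
    input: InputConfig
    output_dir: str
    seed: int = 0
    stopword_file: str | None = None
    min_tokens: int = 5
    keep_numbers: bool = True
    phases: tuple[PhaseDefinition, ...] = DEFAULT_PHASES
    embedding: EmbeddingConfig = EmbeddingConfig()
    lda: LdaConfig = LdaConfig()
    fusion: FusionConfig = FusionConfig()
    clustering: ClusteringConfig = ClusteringConfig()
    evolution: EvolutionConfig = EvolutionConfig()
    novelty: NoveltyConfig = NoveltyConfig()


_SECTION_TYPES = {
    "input": InputConfig,
    "embedding": EmbeddingConfig,
    "lda": LdaConfig,
    "fusion": FusionConfig,
    "clustering": ClusteringConfig,
    "evolution": EvolutionConfig,
    "novelty": NoveltyConfig,
}
_TOP_SCALARS = ("output_dir", "seed", "stopword_file", "min_tokens", "keep_numbers", "phases")


def _coerce_section(name: str, cls, data: Mapping[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
        else:
            logger.info("config: %s.%s defaulted", name, f.name)
    return cls(**kwargs)


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    known = set(_SECTION_TYPES) | set(_TOP_SCALARS)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    if "input" not in data:
        raise ConfigurationError("missing required key 'input'")
    if "output_dir" not in data:
        raise ConfigurationError("missing required key 'output_dir'")

    sections = {
        name: _coerce_section(name, cls, data.get(name) or {})
        for name, cls in _SECTION_TYPES.items()
    }
    phases = DEFAULT_PHASES
    if "phases" in data:
        phases = tuple(
            PhaseDefinition(p["label"], int(p["start"]), int(p["end"])) for p in data["phases"]
        )
    validate_phases(phases)
    cfg = PipelineConfig(
        input=sections["input"],
        output_dir=str(data["output_dir"]),
        seed=int(data.get("seed", 0)),
        stopword_file=data.get("stopword_file"),
        min_tokens=int(data.get("min_tokens", 5)),
        keep_numbers=bool(data.get("keep_numbers", True)),
        phases=phases,
        embedding=sections["embedding"],
        lda=sections["lda"],
        fusion=sections["fusion"],
        clustering=sections["clustering"],
        evolution=sections["evolution"],
        novelty=sections["novelty"],
    )
    _check_values(cfg)
    return cfg


def _check_values(cfg: PipelineConfig) -> None:
    if cfg.input.format.startswith("preset:"):
        pass  # synthetic input: no file needed
    elif not cfg.input.path:
        raise ConfigurationError("input.path must be set")
    elif not Path(cfg.input.path).exists():
        raise ConfigurationError(f"input file does not exist: {cfg.input.path}")
    if cfg.stopword_file and not Path(cfg.stopword_file).exists():
        raise ConfigurationError(f"stopword file does not exist: {cfg.stopword_file}")
    if cfg.embedding.pairs_file and not Path(cfg.embedding.pairs_file).exists():
        raise ConfigurationError(f"pairs file does not exist: {cfg.embedding.pairs_file}")
    if cfg.lda.k_min < 2 or cfg.lda.k_max < cfg.lda.k_min:
        raise ConfigurationError("lda.k_min/k_max invalid")
    if cfg.clustering.k_min < 2 or cfg.clustering.k_max < cfg.clustering.k_min:
        raise ConfigurationError("clustering.k_min/k_max invalid")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML configuration file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        return obj

    out = {
        "input": clean(cfg.input),
        "output_dir": cfg.output_dir,
        "seed": cfg.seed,
        "stopword_file": cfg.stopword_file,
        "min_tokens": cfg.min_tokens,
        "keep_numbers": cfg.keep_numbers,
        "phases": [
            {"label": p.label, "start": p.start_year, "end": p.end_year} for p in cfg.phases
        ],
    }
    for name in ("embedding", "lda", "fusion", "clustering", "evolution", "novelty"):
        out[name] = clean(getattr(cfg, name))
    return out


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
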