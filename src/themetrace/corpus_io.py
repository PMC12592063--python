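"""Reading, cleaning, and phase-segmenting time-stamped bibliographic records.

A corpus is a table of articles (identifier, title, abstract, publication
year).  Ingestion drops records without an abstract or with an unparseable
year and reports the counts; cleaning lowercases title + abstract, splits on
runs of non-alphanumeric characters, and removes stop words; segmentation
buckets documents into non-overlapping year phases.
"""
from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, EmptyCorpusError, SchemaError

logger = logging.getLogger(__name__)

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")

#: Default mapping from logical field -> column name for generic CSV input.
DEFAULT_COLUMN_MAP = {"doc_id": "doc_id", "title": "title", "abstract": "abstract", "year": "year"}

#: Column mapping for a Web of Science tab-delimited export (field tags).
WOS_COLUMN_MAP = {"doc_id": "UT", "title": "TI", "abstract": "AB", "year": "PY"}


@dataclass(frozen=True)
class DocumentRecord:
    """One bibliographic item: the atomic unit flowing through every stage."""

    doc_id: str
    title: str
    abstract: str
    year: int


@dataclass(frozen=True)
class TokenizedDocument:
    """A cleaned document: lowercase tokens from title followed by abstract."""

    doc_id: str
    tokens: tuple[str, ...]
    year: int


@dataclass(frozen=True)
class PhaseDefinition:
    """A labelled, inclusive year range."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ConfigurationError(
                f"phase {self.label!r}: start_year {self.start_year} > end_year {self.end_year}"
            )

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


#: The four developmental phases used throughout: an emergent decade, an early
#: expansion span, a consolidation span, and the most recent high-output span.
DEFAULT_PHASES: tuple[PhaseDefinition, ...] = (
    PhaseDefinition("1995-2004", 1995, 2004),
    PhaseDefinition("2005-2013", 2005, 2013),
    PhaseDefinition("2014-2019", 2014, 2019),
    PhaseDefinition("2020-2024", 2020, 2024),
)

UNASSIGNED = "unassigned"


def validate_phases(phases: Sequence[PhaseDefinition]) -> None:
    """Raise :class:`ConfigurationError` unless phases are ordered and disjoint."""
    ordered = sorted(phases, key=lambda p: p.start_year)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_year <= a.end_year:
            raise ConfigurationError(f"phases {a.label!r} and {b.label!r} overlap")


def load_stopwords(path: str | Path | None = None, extra: Iterable[str] = ()) -> frozenset[str]:
    """Load the active stop-word list.

    With no ``path`` the packaged standard English list is used.  ``extra``
    words are merged in.  The resulting list's SHA-256 content hash is logged
    so a run can be tied to the exact list it used.
    """
    if path is None:
        text = resources.files("themetrace.data").joinpath("stopwords_en.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    words = {w.strip().lower() for w in text.splitlines() if w.strip()}
    words |= {w.lower() for w in extra}
    digest = hashlib.sha256("\n".join(sorted(words)).encode()).hexdigest()
    logger.info("active stop-word list: %d words, sha256=%s", len(words), digest)
    return frozenset(words)


def _read_rows(path: Path, fmt: str) -> tuple[list[dict], list[str]]:
    delim = "\t" if fmt == "wos_tab" else ","
    with open(path, newline="", encoding="utf-8-sig") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        fieldnames = list(reader.fieldnames or [])
        return list(reader), fieldnames


def read_corpus(
    path: str | Path,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[DocumentRecord], dict[str, int]]:
    """Read a bibliographic table and filter unusable records.

    Parameters
    ----------
    path:
        CSV (RFC 4180) or tab-delimited Web-of-Science-style export.
    format:
        ``"csv"`` or ``"wos_tab"``.
    column_map:
        Mapping of logical names (``doc_id``, ``title``, ``abstract``,
        ``year``) to column names.  ``doc_id`` is optional; missing ids are
        synthesized from the row number.

    Returns
    -------
    records, exclusion_report
        Records in file order, and counts of excluded rows by reason
        (``no_abstract``, ``bad_year``).
    """
    if format not in ("csv", "wos_tab"):
        raise ConfigurationError(f"unknown corpus format {format!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"corpus file not found: {path}")
    cmap = dict(WOS_COLUMN_MAP if format == "wos_tab" else DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    rows, fieldnames = _read_rows(path, format)
    for logical in ("title", "abstract", "year"):
        if cmap[logical] not in fieldnames:
            raise SchemaError(
                f"mapped column {cmap[logical]!r} (for {logical!r}) not in header {fieldnames}"
            )
    has_id = cmap.get("doc_id") in fieldnames

    records: list[DocumentRecord] = []
    report = {"no_abstract": 0, "bad_year": 0}
    seen_ids: set[str] = set()
    for i, row in enumerate(rows):
        abstract = (row.get(cmap["abstract"]) or "").strip()
        if not abstract:
            report["no_abstract"] += 1
            continue
        raw_year = (row.get(cmap["year"]) or "").strip()
        try:
            year = int(float(raw_year))
        except ValueError:
            report["bad_year"] += 1
            continue
        doc_id = (row.get(cmap["doc_id"]) or "").strip() if has_id else ""
        if not doc_id:
            doc_id = f"row{i:06d}"
        if doc_id in seen_ids:
            raise SchemaError(f"duplicate doc_id {doc_id!r}")
        seen_ids.add(doc_id)
        records.append(DocumentRecord(doc_id, (row.get(cmap["title"]) or "").strip(), abstract, year))
    if not records:
        raise EmptyCorpusError(f"no usable records in {path} (excluded: {report})")
    return records, report


def preprocess(
    record: DocumentRecord,
    stopwords: frozenset[str] | set[str] = frozenset(),
    *,
    keep_numbers: bool = True,
) -> TokenizedDocument:
    """Clean one record into a token list.

    Title and abstract are joined (title first), lowercased, and split on
    every maximal run of non-alphanumeric characters.  Stop words are removed.
    Pure-digit tokens are kept by default (they can carry signal, e.g. the
    "19" of "covid 19") but can be dropped with ``keep_numbers=False``.
    Degenerate inputs yield an empty token list rather than an error.
    """
    text = f"{record.title} {record.abstract}".lower()
    tokens = [t for t in _TOKEN_SPLIT.split(text) if t and t not in stopwords]
    if not keep_numbers:
        tokens = [t for t in tokens if not t.isdigit()]
    return TokenizedDocument(record.doc_id, tuple(tokens), record.year)


def preprocess_corpus(
    records: Sequence[DocumentRecord],
    stopwords: frozenset[str] | set[str] = frozenset(),
    *,
    keep_numbers: bool = True,
    min_tokens: int = 5,
) -> tuple[list[TokenizedDocument], list[TokenizedDocument]]:
    """Clean every record; split off documents with fewer than ``min_tokens``.

    Returns ``(kept, flagged)``.  Flagged documents are excluded from model
    training downstream (a near-empty bag-of-words row carries no signal);
    the count is logged.
    """
    docs = [preprocess(r, stopwords, keep_numbers=keep_numbers) for r in records]
    kept = [d for d in docs if len(d.tokens) >= min_tokens]
    flagged = [d for d in docs if len(d.tokens) < min_tokens]
    if flagged:
        logger.warning("%d documents below the %d-token minimum were flagged", len(flagged), min_tokens)
    return kept, flagged


def segment_by_phase(
    docs: Sequence[TokenizedDocument],
    phases: Sequence[PhaseDefinition] = DEFAULT_PHASES,
) -> dict[str, list[TokenizedDocument]]:
    """Partition documents into phases by publication year.

    Every document lands in exactly one phase, or in the ``"unassigned"``
    overflow bucket when its year falls outside every phase (a warning is
    logged).  Within-phase input order is preserved.
    """
    validate_phases(phases)
    buckets: dict[str, list[TokenizedDocument]] = {p.label: [] for p in phases}
    buckets[UNASSIGNED] = []
    for doc in docs:
        for phase in phases:
            if phase.contains(doc.year):
                buckets[phase.label].append(doc)
                break
        else:
            buckets[UNASSIGNED].append(doc)
    if buckets[UNASSIGNED]:
        logger.warning("%d documents fell outside all phases", len(buckets[UNASSIGNED]))
    return buckets


# ---------------------------------------------------------------------------
# persistence


def write_tokens_jsonl(docs: Sequence[TokenizedDocument], path: str | Path) -> None:
    """Persist the cleaned corpus, one JSON object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({"doc_id": d.doc_id, "year": d.year, "tokens": list(d.tokens)}) + "\n")


def read_tokens_jsonl(path: str | Path) -> list[TokenizedDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            docs.append(TokenizedDocument(obj["doc_id"], tuple(obj["tokens"]), int(obj["year"])))
    return docs


def write_exclusion_report(report: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reason", "count"])
        for reason in sorted(report):
            writer.writerow([reason, report[reason]])
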