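"""Deterministic seeds and content hashes used across the pipeline."""
from __future__ import annotations

import hashlib
from pathlib import Path


def stable_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from one global seed.

    The derivation hashes the stage name, so any stage can be rerun in
    isolation with the same seed it saw inside a full run.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
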