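"""Local keyed store of isolation-source metadata.

Each database record (keyed by GI number or accession.version) carries
the free-text "isolation source" field from its submission and, when
available, the PubMed identifier of the associated study.  The store is
a single SQLite file so lookups need no network; a builder turns a
3-column TSV into a store for fixtures or locally harvested data.

Schema (version 1)::

    CREATE TABLE annotations (
        record_id        TEXT PRIMARY KEY,
        isolation_source TEXT NOT NULL,
        pubmed_id        TEXT
    );
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import StoreError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE annotations (
    record_id        TEXT PRIMARY KEY,
    isolation_source TEXT NOT NULL,
    pubmed_id        TEXT
);
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
"""


@dataclass(frozen=True)
class RecordAnnotation:
    """Isolation-source text (non-empty) and optional PubMed id of a record."""

    record_id: str
    isolation_source: str
    pubmed_id: str | None = None


class MetadataStore:
    """Read-only handle over the SQLite annotation store."""

    def __init__(self, path):
        path = Path(path)
        if not path.exists():
            raise StoreError(
                f"metadata store not found: {path}; build one from a "
                "3-column TSV with envotag.metadata_store.build_store"
            )
        self._conn = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
        try:
            cols = {row[1] for row in self._conn.execute("PRAGMA table_info(annotations)")}
        except sqlite3.DatabaseError as exc:
            raise StoreError(f"{path}: not an SQLite database: {exc}") from exc
        expected = {"record_id", "isolation_source", "pubmed_id"}
        if not expected <= cols:
            raise StoreError(
                f"{path}: unexpected schema (columns {sorted(cols)}); "
                f"expected table 'annotations' with columns {sorted(expected)}"
            )

    def lookup_many(self, ids: Iterable[str]) -> dict[str, RecordAnnotation]:
        """Fetch annotations for the given record ids.

        Only ids present with a non-empty isolation source appear in the
        result; misses are dropped silently (logged at debug level).
        """
        out: dict[str, RecordAnnotation] = {}
        for record_id in ids:
            row = self._conn.execute(
                "SELECT isolation_source, pubmed_id FROM annotations WHERE record_id = ?",
                (record_id,),
            ).fetchone()
            if row is None or not row[0]:
                logger.debug("record %s: no isolation source; discarded", record_id)
                continue
            out[record_id] = RecordAnnotation(record_id, row[0], row[1] or None)
        return out

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "MetadataStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_store(path) -> MetadataStore:
    """Open an existing store read-only; errors carry a remediation hint."""
    return MetadataStore(path)


def build_store(tsv_path, out_path) -> Path:
    """Build a store from a 3-column TSV (record_id, isolation_source, pubmed_id).

    The pubmed column may be blank.  An optional single header line
    starting with ``record_id`` is skipped.  Duplicate record ids are an
    error.
    """
    out_path = Path(out_path)
    if out_path.exists():
        out_path.unlink()
    rows: list[tuple[str, str, str | None]] = []
    seen: set[str] = set()
    with open(tsv_path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if line_no == 1 and fields[0] == "record_id":
                continue
            if len(fields) < 2:
                raise StoreError(f"{tsv_path}: line {line_no}: expected 3 columns")
            record_id, isolation = fields[0], fields[1]
            pubmed = fields[2] if len(fields) > 2 and fields[2] else None
            if record_id in seen:
                raise StoreError(f"{tsv_path}: line {line_no}: duplicate record id {record_id!r}")
            seen.add(record_id)
            rows.append((record_id, isolation, pubmed))
    conn = sqlite3.connect(out_path)
    with conn:
        conn.executescript(_SCHEMA)
        conn.execute(
            "INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),)
        )
        conn.executemany("INSERT INTO annotations VALUES (?, ?, ?)", rows)
    conn.close()
    return out_path
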