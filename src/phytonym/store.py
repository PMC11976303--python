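"""Embedded persistence for summary records.

Records live in a single-table SQLite database keyed by ``recordID``;
the in-memory index structures are rebuilt from the stored records on
load, which is cheap at desk scale.  ``:memory:`` works for ephemeral
use.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path
from typing import Iterable, Sequence

from .nameindex import SummaryRecord, rows_to_records

_SCHEMA = """
CREATE TABLE IF NOT EXISTS summary_records (
    recordID INTEGER PRIMARY KEY,
    taxonID TEXT NOT NULL DEFAULT '',
    datasetID TEXT NOT NULL DEFAULT '',
    scientificName TEXT NOT NULL,
    scientificNameAuthorship TEXT NOT NULL DEFAULT '',
    taxonRank TEXT NOT NULL DEFAULT '',
    taxonomicStatus TEXT NOT NULL DEFAULT '',
    acceptedNameUsageID TEXT NOT NULL DEFAULT '',
    parentNameUsageID TEXT NOT NULL DEFAULT '',
    namePublishedInYear TEXT NOT NULL DEFAULT '',
    higherClassification TEXT NOT NULL DEFAULT '',
    isVernacular INTEGER NOT NULL DEFAULT 0
);
"""

_COLS = (
    "recordID", "taxonID", "datasetID", "scientificName",
    "scientificNameAuthorship", "taxonRank", "taxonomicStatus",
    "acceptedNameUsageID", "parentNameUsageID", "namePublishedInYear",
    "higherClassification", "isVernacular",
)


class RecordStore:
    """SQLite-backed record store."""

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "RecordStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def _next_id(self) -> int:
        row = self._conn.execute(
            "SELECT COALESCE(MAX(recordID), 0) FROM summary_records"
        ).fetchone()
        return int(row[0]) + 1

    def add_rows(self, rows: Iterable[dict]) -> int:
        """Append ingest rows (see :func:`phytonym.nameindex.read_taxon_table`);
        returns the number of records created."""
        records = rows_to_records(rows, start_id=self._next_id())
        self.add_records(records)
        return len(records)

    def add_records(self, records: Sequence[SummaryRecord]) -> None:
        self._conn.executemany(
            f"INSERT INTO summary_records ({', '.join(_COLS)}) "
            f"VALUES ({', '.join('?' * len(_COLS))})",
            [
                tuple(
                    int(v) if c == "isVernacular" else v
                    for c, v in ((c, getattr(r, c)) for c in _COLS)
                )
                for r in records
            ],
        )
        self._conn.commit()

    def load_records(self) -> list[SummaryRecord]:
        rows = self._conn.execute(
            f"SELECT {', '.join(_COLS)} FROM summary_records ORDER BY recordID"
        ).fetchall()
        return [
            SummaryRecord(
                **{**dict(zip(_COLS, row)), "isVernacular": bool(row[-1])}
            )
            for row in rows
        ]

    def __len__(self) -> int:
        return int(
            self._conn.execute("SELECT COUNT(*) FROM summary_records").fetchone()[0]
        )

    def clear(self) -> None:
        self._conn.execute("DELETE FROM summary_records")
        self._conn.commit()
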