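"""Batch-file input and report output.

Matching and parsing submissions arrive as one-column CSV files with a
``scientificName`` header (the template-file workflow); reports go out
as CSV with a fixed, documented column set, optionally as a spreadsheet
for parity with the hosted service's returned Excel files.  A reader for
single-name-column test workbooks (.xlsx) is provided for the published
benchmark test sets; the chosen name column is logged.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import BatchLimitError, SchemaError
from .matcher import MatchResult
from .parser import ParsedName

log = logging.getLogger(__name__)

MATCH_REPORT_COLUMNS = (
    "query", "status", "matchedName", "matchedAuthorship", "similarity",
    "totalDistance", "datasetID", "taxonID", "stageUsed",
)
PARSE_REPORT_COLUMNS = (
    "parseRemark", "scientificName", "genusOrAbove", "specificEpithet",
    "rankMarker", "infraspecificEpithet", "scientificNameAuthorship",
    "namePublishedInYear",
)


def read_name_csv(path: str | Path, limit: int | None = None) -> list[str]:
    """Names from the first ``scientificName`` column of a CSV file.

    The header match is case-insensitive; blank rows are skipped and
    counted in the log.  ``limit`` enforces the batch submission bound.
    """
    path = Path(path)
    with path.open(encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, missing header: scientificName")
        col = next(
            (i for i, h in enumerate(header) if h.strip().casefold() == "scientificname"),
            None,
        )
        if col is None:
            raise SchemaError(f"{path}: missing header: scientificName")
        names: list[str] = []
        skipped = 0
        for row in reader:
            value = row[col].strip() if col < len(row) else ""
            if value:
                names.append(value)
            else:
                skipped += 1
    if skipped:
        log.info("%s: skipped %d blank row(s)", path, skipped)
    if limit is not None and len(names) > limit:
        raise BatchLimitError(len(names), limit)
    return names


def read_name_workbook(path: str | Path, sheet: int = 0) -> list[str]:
    """Names from the first plausible name column of an .xlsx test workbook.

    The column whose header case-folds to ``scientificname`` (or ``name``)
    wins; failing that, the first column holding mostly non-numeric text.
    The choice is logged.
    """
    frame = pd.read_excel(path, sheet_name=sheet, dtype=str).fillna("")
    chosen = None
    for col in frame.columns:
        if str(col).strip().casefold() in ("scientificname", "name"):
            chosen = col
            break
    if chosen is None:
        for col in frame.columns:
            values = [v for v in frame[col].astype(str) if v.strip()]
            texty = sum(1 for v in values if any(c.isalpha() for c in v))
            if values and texty / len(values) > 0.8:
                chosen = col
                break
    if chosen is None:
        raise SchemaError(f"{path}: no name column detected")
    log.info("%s: using column %r as the name column", path, chosen)
    return [v.strip() for v in frame[chosen].astype(str) if v.strip()]


def _match_report_frame(results: Sequence[MatchResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        best = res.best
        rows.append(
            {
                "query": res.query,
                "status": res.status,
                "matchedName": best.record.scientificName if best else "",
                "matchedAuthorship": best.record.scientificNameAuthorship if best else "",
                "similarity": round(best.similarity, 4) if best else "",
                "totalDistance": best.total_distance if best else "",
                "datasetID": best.record.datasetID if best else "",
                "taxonID": best.record.taxonID if best else "",
                "stageUsed": res.stage_used,
            }
        )
    return pd.DataFrame(rows, columns=list(MATCH_REPORT_COLUMNS))


def write_match_report(
    results: Sequence[MatchResult], path: str | Path, xlsx: bool = False
) -> None:
    """Write the matching report (top candidate per query)."""
    frame = _match_report_frame(results)
    if xlsx:
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


def _parse_report_frame(results: Sequence[ParsedName]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.as_dict() for r in results], columns=list(PARSE_REPORT_COLUMNS)
    )


def write_parse_report(
    results: Sequence[ParsedName], path: str | Path, xlsx: bool = False
) -> None:
    frame = _parse_report_frame(results)
    if xlsx:
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


def write_find_report(matches, path: str | Path) -> None:
    """CSV of text matches: scientificName, startIndex, endIndex, rank, status."""
    pd.DataFrame(
        [
            {
                "scientificName": m.scientificName,
                "startIndex": m.startIndex,
                "endIndex": m.endIndex,
                "taxonRank": m.taxonRank,
                "taxonomicStatus": m.taxonomicStatus,
            }
            for m in matches
        ],
        columns=["scientificName", "startIndex", "endIndex", "taxonRank", "taxonomicStatus"],
    ).to_csv(path, index=False)
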