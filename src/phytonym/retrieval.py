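"""Faceted name retrieval, autocomplete and record detail.

Retrieval is a browse operation: the query is split into tokens and a
record matches when every query token is a case-folded prefix of some
token of its name.  Hits can be filtered conjunctively by publication
year (single year or closed range), rank, status and dataset, with
vernacular records excluded unless requested.  Results are sorted
ascending by name length (then name, then record ID), paginated, and
accompanied by facet counts over rank, status, year and dataset — each
facet dimension's counts sum to the total hit count.

Edit-distance fuzziness deliberately lives in the matcher, not here; a
config flag on :func:`retrieve` enables distance-1 token prefixes for
parity experiments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .config import DEFAULT_CONFIG, ToolkitConfig
from .distance import levenshtein
from .errors import RecordNotFoundError
from .nameindex import NameIndex, SummaryRecord
from .normalize import normalize_with_config

FACET_DIMENSIONS = ("taxonRank", "taxonomicStatus", "namePublishedInYear", "datasetID")


@dataclass
class RetrievalQuery:
    queryText: str = ""
    yearFilter: tuple[int, int] | int | None = None
    rankFilter: set[str] | None = None
    statusFilter: set[str] | None = None
    datasetFilter: set[str] | None = None
    includeVernacular: bool = False
    page: int = 1
    pageSize: int = 0  # 0 → config default

    def __post_init__(self) -> None:
        if self.page < 1:
            raise ValueError("page must be >= 1")


@dataclass
class ResultPage:
    hits: list[SummaryRecord]
    totalHits: int
    facets: dict[str, dict[str, int]]
    page: int
    pageSize: int


def _year_ok(value: str, yf: tuple[int, int] | int | None) -> bool:
    if yf is None:
        return True
    if not value or not value.strip().isdigit():
        return False  # records without a year drop out under an active filter
    y = int(value)
    if isinstance(yf, int):
        return y == yf
    lo, hi = yf
    return lo <= y <= hi


def _token_matches(qtok: str, name_tokens: Sequence[str], fuzzy: bool) -> bool:
    for nt in name_tokens:
        if nt.startswith(qtok):
            return True
        if fuzzy and levenshtein(qtok, nt[: len(qtok)], limit=1) <= 1:
            return True
    return False


def retrieve(
    q: RetrievalQuery,
    index: NameIndex,
    config: ToolkitConfig = DEFAULT_CONFIG,
    fuzzy_tokens: bool = False,
) -> ResultPage:
    """Run a faceted retrieval query against the index."""
    page_size = q.pageSize or config.default_page_size
    page_size = min(page_size, config.max_page_size)
    tokens = normalize_with_config(q.queryText, config).casefold().split()
    has_filters = any(
        f is not None for f in (q.yearFilter, q.rankFilter, q.statusFilter, q.datasetFilter)
    )
    if not tokens and not has_filters:
        return ResultPage([], 0, {dim: {} for dim in FACET_DIMENSIONS}, q.page, page_size)

    hits: list[SummaryRecord] = []
    for rec in index.records:
        if rec.isVernacular and not q.includeVernacular:
            continue
        if not _year_ok(rec.namePublishedInYear, q.yearFilter):
            continue
        if q.rankFilter is not None and rec.taxonRank not in q.rankFilter:
            continue
        if q.statusFilter is not None and rec.taxonomicStatus not in q.statusFilter:
            continue
        if q.datasetFilter is not None and rec.datasetID not in q.datasetFilter:
            continue
        if tokens:
            name_tokens = rec.scientificName.casefold().split(" ")
            if not all(_token_matches(t, name_tokens, fuzzy_tokens) for t in tokens):
                continue
        hits.append(rec)

    hits.sort(key=lambda r: (len(r.scientificName), r.scientificName.casefold(), r.recordID))
    facets = {
        dim: dict(Counter(str(getattr(r, dim)) for r in hits))
        for dim in FACET_DIMENSIONS
    }
    start = (q.page - 1) * page_size
    return ResultPage(hits[start : start + page_size], len(hits), facets, q.page, page_size)


def suggest(
    prefix_text: str,
    limit: int,
    index: NameIndex,
    config: ToolkitConfig = DEFAULT_CONFIG,
) -> list[str]:
    """Autocomplete: indexed names starting with the typed prefix,
    shortest (then lexicographically smallest) first."""
    prefix = normalize_with_config(prefix_text, config).casefold()
    if not prefix or limit < 1:
        return []
    seen: set[str] = set()
    names: list[str] = []
    for rec in index.records:
        if rec.isVernacular:
            continue
        key = rec.scientificName.casefold()
        if key.startswith(prefix) and key not in seen:
            seen.add(key)
            names.append(rec.scientificName)
    names.sort(key=lambda s: (len(s), s.casefold()))
    return names[:limit]


@dataclass
class DetailResult:
    record: SummaryRecord
    acceptedName: str
    acceptedRecord: SummaryRecord | None
    lineage: list[str]
    warning: str = ""


def detail(
    record_id: int,
    source: NameIndex | Mapping[int, SummaryRecord],
) -> DetailResult:
    """Full detail for one record: accepted-name resolution and lineage.

    Follows ``acceptedNameUsageID`` to the accepted record within the
    same dataset; lineage is the ``higherClassification`` string when
    present, otherwise the ``parentNameUsageID`` chain root-first.
    Cycle-safe; a dangling accepted link yields a warning, an unknown
    record ID raises :class:`RecordNotFoundError`.
    """
    records = source.records_by_id if isinstance(source, NameIndex) else source
    rec = records.get(record_id)
    if rec is None:
        raise RecordNotFoundError(f"no record with recordID {record_id}")

    by_taxon: dict[tuple[str, str], SummaryRecord] = {}
    for r in records.values():
        if not r.isVernacular and r.taxonID:
            by_taxon.setdefault((r.datasetID, r.taxonID), r)

    warning = ""
    accepted: SummaryRecord | None = rec if not rec.acceptedNameUsageID else None
    if rec.acceptedNameUsageID:
        accepted = by_taxon.get((rec.datasetID, rec.acceptedNameUsageID))
        if accepted is None:
            warning = (
                f"acceptedNameUsageID {rec.acceptedNameUsageID!r} does not resolve "
                f"within dataset {rec.datasetID!r}"
            )

    if rec.higherClassification:
        lineage = [p.strip() for p in rec.higherClassification.split("|") if p.strip()]
    else:
        lineage = []
        seen = {record_id}
        cur = rec
        while cur.parentNameUsageID:
            parent = by_taxon.get((cur.datasetID, cur.parentNameUsageID))
            if parent is None or parent.recordID in seen:
                break
            lineage.append(parent.scientificName)
            seen.add(parent.recordID)
            cur = parent
        lineage.reverse()  # root-first

    return DetailResult(
        record=rec,
        acceptedName=accepted.scientificName if accepted else "",
        acceptedRecord=accepted,
        lineage=lineage,
        warning=warning,
    )
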