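"""The integrated name summary table and its in-memory indexes.

Taxon tables from any number of source datasets are ingested into one
set of :class:`SummaryRecord` rows shaped after the Darwin Core taxon
terms, with per-dataset provenance.  :class:`NameIndex` builds the four
query structures every service uses:

* ``exactSet`` — case-folded full name → record IDs;
* a token-prefix trie answering "how many distinct indexed names start
  with this token sequence" (the free-text finder's primitive);
* per-token fuzzy lookup via symmetric-delete candidate generation and a
  bounded Levenshtein verify (the matcher's primitive);
* facet metadata (rank / status / year / dataset) for retrieval.

Fuzzy semantics are per token: a query hits an indexed name when both
have the same number of space-separated tokens and every aligned token
pair is within Levenshtein distance ``d``.  A whole-string mode (one
edit budget across the entire name) is available for comparison.
Candidate generation is an implementation detail; the contract is
completeness against a brute-force scan, which the test suite enforces
with an independent alignment library.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from .distance import deletion_variants, levenshtein
from .errors import SchemaError
from .normalize import normalize_name

log = logging.getLogger(__name__)

#: Darwin Core columns recognized on ingest (case-insensitive header match).
DWC_COLUMNS = (
    "taxonID",
    "scientificName",
    "scientificNameAuthorship",
    "taxonRank",
    "taxonomicStatus",
    "acceptedNameUsageID",
    "parentNameUsageID",
    "namePublishedInYear",
    "higherClassification",
    "isVernacular",
)

_TRUTHY = {"1", "true", "t", "yes", "y"}


@dataclass
class SummaryRecord:
    """One row of the integrated name summary table."""

    recordID: int
    taxonID: str
    datasetID: str
    scientificName: str
    scientificNameAuthorship: str = ""
    taxonRank: str = ""
    taxonomicStatus: str = ""
    acceptedNameUsageID: str = ""
    parentNameUsageID: str = ""
    namePublishedInYear: str = ""
    higherClassification: str = ""
    isVernacular: bool = False

    def as_dict(self) -> dict[str, object]:
        return {
            "recordID": self.recordID,
            "taxonID": self.taxonID,
            "datasetID": self.datasetID,
            "scientificName": self.scientificName,
            "scientificNameAuthorship": self.scientificNameAuthorship,
            "taxonRank": self.taxonRank,
            "taxonomicStatus": self.taxonomicStatus,
            "acceptedNameUsageID": self.acceptedNameUsageID,
            "parentNameUsageID": self.parentNameUsageID,
            "namePublishedInYear": self.namePublishedInYear,
            "higherClassification": self.higherClassification,
            "isVernacular": self.isVernacular,
        }


class FuzzyHit(NamedTuple):
    record_id: int
    token_distances: tuple[int, ...]
    total_distance: int


def read_taxon_table(path: str | Path, dataset_id: str) -> tuple[list[dict], int]:
    """Read a DwC-style CSV/TSV into row dicts; returns (rows, skipped).

    The delimiter is taken from the extension (``.tsv``/``.tab`` → tab)
    or sniffed from the header line.  A missing ``scientificName``
    header raises :class:`SchemaError`; rows with a blank name are
    skipped and counted.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    lines = text.splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty file, missing required column: scientificName")
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") or "\t" in lines[0] else ","
    reader = csv.reader(lines, delimiter=delimiter)
    header = next(reader)
    colmap: dict[str, int] = {}
    canon = {c.casefold(): c for c in DWC_COLUMNS}
    for pos, name in enumerate(header):
        key = name.strip().casefold()
        if key in canon and canon[key] not in colmap:
            colmap[canon[key]] = pos
    if "scientificName" not in colmap:
        raise SchemaError(f"{path}: missing required column: scientificName")
    rows: list[dict] = []
    skipped = 0
    for raw in reader:
        if not any(cell.strip() for cell in raw):
            continue
        row = {
            col: (raw[pos].strip() if pos < len(raw) else "")
            for col, pos in colmap.items()
        }
        if not row.get("scientificName", ""):
            skipped += 1
            continue
        row["datasetID"] = dataset_id
        rows.append(row)
    if skipped:
        log.info("%s: skipped %d row(s) lacking scientificName", path, skipped)
    return rows, skipped


def rows_to_records(rows: Iterable[dict], start_id: int = 1) -> list[SummaryRecord]:
    """Materialize row dicts as :class:`SummaryRecord`, normalizing names."""
    records = []
    rid = start_id
    for row in rows:
        records.append(
            SummaryRecord(
                recordID=rid,
                taxonID=row.get("taxonID", ""),
                datasetID=row.get("datasetID", ""),
                scientificName=normalize_name(row["scientificName"]),
                scientificNameAuthorship=normalize_name(
                    row.get("scientificNameAuthorship", "")
                ),
                taxonRank=row.get("taxonRank", ""),
                taxonomicStatus=row.get("taxonomicStatus", ""),
                acceptedNameUsageID=row.get("acceptedNameUsageID", ""),
                parentNameUsageID=row.get("parentNameUsageID", ""),
                namePublishedInYear=row.get("namePublishedInYear", ""),
                higherClassification=row.get("higherClassification", ""),
                isVernacular=str(row.get("isVernacular", "")).strip().casefold()
                in _TRUTHY,
            )
        )
        rid += 1
    return records


def ingest_records(path: str | Path, dataset_id: str, store=None) -> int:
    """Ingest a taxon table; returns the number of records created.

    With ``store`` (a :class:`phytonym.store.RecordStore`), records are
    appended there with store-assigned IDs; otherwise use
    :func:`read_taxon_table` / :func:`rows_to_records` directly.
    """
    rows, _skipped = read_taxon_table(path, dataset_id)
    if store is not None:
        return store.add_rows(rows)
    return len(rows)


class _TrieNode:
    __slots__ = ("count", "children")

    def __init__(self) -> None:
        self.count = 0
        self.children: dict[str, _TrieNode] = {}


def _prefix_key(token: str, first: bool) -> str:
    # Genus initial stays case-sensitive; everything else case-folds.
    if first and token:
        return token[0] + token[1:].casefold()
    return token.casefold()


class NameIndex:
    """Query structures over a set of :class:`SummaryRecord`.

    Vernacular records are reachable through exact lookup only; the
    prefix trie and the fuzzy structures cover scientific names.
    """

    def __init__(self, records: Sequence[SummaryRecord]):
        self.records: list[SummaryRecord] = list(records)
        self.records_by_id: dict[int, SummaryRecord] = {
            r.recordID: r for r in self.records
        }
        self._exact: dict[str, list[int]] = defaultdict(list)
        self._root = _TrieNode()
        # token-count bucket -> {casefolded token tuple: [record ids]}
        self._buckets: dict[int, dict[tuple[str, ...], list[int]]] = defaultdict(
            lambda: defaultdict(list)
        )
        # (token-count, position) -> {deletion variant: {tokens}}
        self._symdel: dict[tuple[int, int], dict[str, set[str]]] = {}
        self._sci_name_keys: set[str] = set()
        trie_seen: set[tuple[str, ...]] = set()
        for rec in self.records:
            key = rec.scientificName.casefold()
            self._exact[key].append(rec.recordID)
            if rec.isVernacular:
                continue
            tokens = rec.scientificName.split(" ")
            folded = tuple(t.casefold() for t in tokens)
            self._buckets[len(folded)][folded].append(rec.recordID)
            self._sci_name_keys.add(key)
            pkeys = tuple(
                _prefix_key(t, first=(k == 0)) for k, t in enumerate(tokens)
            )
            if pkeys in trie_seen:
                continue
            trie_seen.add(pkeys)
            node = self._root
            node.count += 1
            for pk in pkeys:
                node = node.children.setdefault(pk, _TrieNode())
                node.count += 1
        for n, bucket in self._buckets.items():
            for pos in range(n):
                vocab = {tt[pos] for tt in bucket}
                variants: dict[str, set[str]] = defaultdict(set)
                for tok in vocab:
                    for var in deletion_variants(tok, 2):
                        variants[var].add(tok)
                self._symdel[(n, pos)] = dict(variants)

    # -- exact -----------------------------------------------------------
    def lookup_exact(self, name: str) -> list[int]:
        """Record IDs whose full normalized name equals ``name`` (case-insensitive)."""
        return list(self._exact.get(name.casefold(), ()))

    @property
    def name_count(self) -> int:
        """Number of distinct indexed scientific names."""
        return len(self._sci_name_keys)

    # -- fuzzy -----------------------------------------------------------
    def _allowed_tokens(self, n: int, pos: int, qtok: str, d: int) -> dict[str, int]:
        """Indexed tokens at (bucket n, position pos) within distance d of qtok."""
        index = self._symdel.get((n, pos), {})
        cands: set[str] = set()
        for var in deletion_variants(qtok, d):
            cands |= index.get(var, set())
        out: dict[str, int] = {}
        for tok in cands:
            dist = levenshtein(qtok, tok, limit=d)
            if dist <= d:
                out[tok] = dist
        return out

    def lookup_fuzzy(self, name: str, d: int, mode: str = "per_token") -> list[FuzzyHit]:
        """Indexed scientific names within distance ``d`` of ``name``.

        ``per_token`` mode requires equal token counts and every aligned
        token within ``d`` edits; ``whole_string`` mode applies one
        ``d``-edit budget to the full string (token distances are then
        reported as a single total).  Results are sorted by total
        distance, then name, then record ID.
        """
        if d not in (1, 2):
            raise ValueError("fuzzy distance d must be 1 or 2")
        if mode == "whole_string":
            return self._lookup_fuzzy_whole(name, d)
        qtokens = [t.casefold() for t in name.split(" ") if t]
        if not qtokens:
            return []
        n = len(qtokens)
        bucket = self._buckets.get(n)
        if not bucket:
            return []
        allowed = []
        for pos, qt in enumerate(qtokens):
            al = self._allowed_tokens(n, pos, qt, d)
            if not al:
                return []
            allowed.append(al)
        hits: list[FuzzyHit] = []
        for tt, ids in bucket.items():
            dists = []
            for pos in range(n):
                dv = allowed[pos].get(tt[pos])
                if dv is None:
                    break
                dists.append(dv)
            else:
                td = tuple(dists)
                total = sum(td)
                hits.extend(FuzzyHit(rid, td, total) for rid in ids)
        return self._sort_hits(hits)

    def _lookup_fuzzy_whole(self, name: str, d: int) -> list[FuzzyHit]:
        q = name.casefold()
        hits: list[FuzzyHit] = []
        seen: set[str] = set()
        for n, bucket in self._buckets.items():
            for tt, ids in bucket.items():
                cand = " ".join(tt)
                if cand in seen:
                    continue
                seen.add(cand)
                dist = levenshtein(q, cand, limit=d)
                if dist <= d:
                    hits.extend(FuzzyHit(rid, (dist,), dist) for rid in ids)
        return self._sort_hits(hits)

    def _sort_hits(self, hits: list[FuzzyHit]) -> list[FuzzyHit]:
        def key(h: FuzzyHit):
            rec = self.records_by_id[h.record_id]
            return (h.total_distance, rec.scientificName.casefold(), h.record_id)

        return sorted(hits, key=key)

    # -- prefix ----------------------------------------------------------
    def phrase_prefix_count(self, tokens: Sequence[str]) -> int:
        """Distinct indexed scientific names whose leading tokens equal
        ``tokens`` (genus initial case-sensitive, otherwise case-folded).
        The empty sequence matches every indexed name."""
        node = self._root
        for k, tok in enumerate(tokens):
            node = node.children.get(_prefix_key(tok, first=(k == 0)))
            if node is None:
                return 0
        return node.count

    # -- facets ----------------------------------------------------------
    def dataset_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for rec in self.records:
            counts[rec.datasetID] += 1
        return dict(counts)


def build_index(records: Sequence[SummaryRecord]) -> NameIndex:
    """Build a :class:`NameIndex`; deterministic for a given record set."""
    return NameIndex(records)
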