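"""The cascading name-matching service.

A submitted name is normalized and pushed through a cascade of lookups,
stopping at the first stage that produces candidates:

1. exact match on the full string (status ``Match``);
2. exact match against vernacular names (status ``Vernacular``);
3. fuzzy match at distance 1, then distance 2 (status ``Recorrect``) —
   under the default per-token semantics each aligned word may differ by
   one (then two) characters: one more, one less, or one different;
4. if the name carries an author citation, the citation is stripped and
   the exact → fuzzy-1 → fuzzy-2 cascade repeats on the name part alone;
5. otherwise the name is ``Unmatch``.

Every candidate carries a similarity coefficient — normalized whole-string
edit similarity, ``1 − Lev(a, b) / max(|a|, |b|)`` on case-folded
strings — and candidates are returned sorted by similarity (descending),
with ties broken by name length, name, configured dataset priority and
record ID so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import DEFAULT_CONFIG, ToolkitConfig
from .distance import levenshtein
from .errors import BatchLimitError
from .nameindex import FuzzyHit, NameIndex, SummaryRecord
from .normalize import normalize_with_config
from .parser import parse_name

STAGES = (
    "exact",
    "vernacular",
    "fuzzy1",
    "fuzzy2",
    "authorship_stripped_exact",
    "authorship_stripped_fuzzy1",
    "authorship_stripped_fuzzy2",
    "none",
)


@dataclass
class MatchCandidate:
    record: SummaryRecord
    total_distance: int
    similarity: float


@dataclass
class MatchResult:
    query: str
    status: str  # Match | Recorrect | Vernacular | Unmatch
    candidates: list[MatchCandidate] = field(default_factory=list)
    stage_used: str = "none"

    @property
    def best(self) -> MatchCandidate | None:
        return self.candidates[0] if self.candidates else None


def similarity(a: str, b: str) -> float:
    """Normalized edit similarity in [0, 1] on case-folded strings.

    1 exactly iff the case-folded strings are equal; 0 iff exactly one
    of them is empty.
    """
    fa, fb = a.casefold(), b.casefold()
    if fa == fb:
        return 1.0
    if not fa or not fb:
        return 0.0
    return 1.0 - levenshtein(fa, fb) / max(len(fa), len(fb))


def _make_candidates(
    index: NameIndex,
    ids_with_distance: Iterable[tuple[int, int]],
    query: str,
    datasets: set[str] | None,
    config: ToolkitConfig,
    vernacular: bool,
) -> list[MatchCandidate]:
    out = []
    for rid, dist in ids_with_distance:
        rec = index.records_by_id[rid]
        if rec.isVernacular != vernacular:
            continue
        if datasets is not None and rec.datasetID not in datasets:
            continue
        out.append(MatchCandidate(rec, dist, similarity(query, rec.scientificName)))
    out.sort(
        key=lambda c: (
            -c.similarity,
            len(c.record.scientificName),
            c.record.scientificName.casefold(),
            config.dataset_priority(c.record.datasetID),
            c.record.recordID,
        )
    )
    return out


def _cascade(
    query: str,
    index: NameIndex,
    datasets: set[str] | None,
    config: ToolkitConfig,
    stripped: bool,
) -> MatchResult | None:
    prefix = "authorship_stripped_" if stripped else ""
    exact = _make_candidates(
        index,
        ((rid, 0) for rid in index.lookup_exact(query)),
        query,
        datasets,
        config,
        vernacular=False,
    )
    if exact:
        return MatchResult(query, "Match", exact, prefix + "exact")
    if not stripped:
        vern = _make_candidates(
            index,
            ((rid, 0) for rid in index.lookup_exact(query)),
            query,
            datasets,
            config,
            vernacular=True,
        )
        if vern:
            return MatchResult(query, "Vernacular", vern, "vernacular")
    for d in (1, 2):
        hits: list[FuzzyHit] = index.lookup_fuzzy(query, d, mode=config.fuzzy_mode)
        cands = _make_candidates(
            index,
            ((h.record_id, h.total_distance) for h in hits),
            query,
            datasets,
            config,
            vernacular=False,
        )
        if cands:
            return MatchResult(query, "Recorrect", cands, f"{prefix}fuzzy{d}")
    return None


def match_name(
    name: str,
    index: NameIndex,
    datasets: Sequence[str] | None = None,
    config: ToolkitConfig = DEFAULT_CONFIG,
) -> MatchResult:
    """Run the full matching cascade for one raw name."""
    query = normalize_with_config(name, config)
    dataset_set = set(datasets) if datasets is not None else None
    if not query:
        return MatchResult(query, "Unmatch")
    result = _cascade(query, index, dataset_set, config, stripped=False)
    if result is not None:
        result.query = query
        return result
    parsed = parse_name(query)
    if parsed.scientificNameAuthorship and parsed.scientificName and (
        parsed.scientificName != query
    ):
        result = _cascade(
            parsed.scientificName, index, dataset_set, config, stripped=True
        )
        if result is not None:
            result.query = query
            return result
    return MatchResult(query, "Unmatch")


def match_batch(
    names: Sequence[str],
    index: NameIndex,
    datasets: Sequence[str] | None = None,
    config: ToolkitConfig = DEFAULT_CONFIG,
) -> list[MatchResult]:
    """Element-wise :func:`match_name`, order preserved.

    Raises :class:`BatchLimitError` when the batch exceeds the
    configured submission limit (1000 names by default).
    """
    if len(names) > config.batch_limit:
        raise BatchLimitError(len(names), config.batch_limit)
    return [match_name(n, index, datasets, config) for n in names]
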