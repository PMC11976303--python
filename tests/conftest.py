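"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's own search paths: edit
distances come from the edlib alignment library and searches are plain
brute-force scans, so agreement with the package is a genuine
cross-check.
"""

from __future__ import annotations

import random
from functools import lru_cache

import edlib
import pytest

from phytonym import build_index, generate_taxonomy
from phytonym.finder import tokenize_text
from phytonym.nameindex import NameIndex, SummaryRecord


@lru_cache(maxsize=1 << 20)
def oracle_distance(a: str, b: str) -> int:
    """Levenshtein distance from an independent alignment library."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def oracle_fuzzy(
    records: list[SummaryRecord], query: str, d: int
) -> set[tuple[int, tuple[int, ...], int]]:
    """Brute-force per-token fuzzy scan over every indexed name."""
    qtoks = [t.casefold() for t in query.split(" ") if t]
    hits = set()
    for rec in records:
        if rec.isVernacular:
            continue
        ntoks = rec.scientificName.casefold().split(" ")
        if len(ntoks) != len(qtoks):
            continue
        dists = []
        for qt, nt in zip(qtoks, ntoks):
            dist = oracle_distance(qt, nt)
            if dist > d:
                break
            dists.append(dist)
        else:
            hits.add((rec.recordID, tuple(dists), sum(dists)))
    return hits


_TERMINAL_PUNCT = ".,;:!?"


def oracle_find(text: str, records: list[SummaryRecord]) -> list[tuple[int, int]]:
    """Slide every indexed name over every token position; then select
    leftmost-longest non-overlapping occurrences.  Returns (start, end)
    character spans."""
    toks = tokenize_text(text)
    names = sorted({r.scientificName for r in records if not r.isVernacular})
    candidates: dict[int, list[tuple[int, int]]] = {}
    for name in names:
        fold = [t.casefold() for t in name.split(" ")]
        for s in range(len(toks) - len(fold) + 1):
            first = toks[s][0]
            if not (first[0].isupper() or first[0] == "×"):
                continue
            end_off = None
            ok = True
            for k, nt in enumerate(fold):
                raw = toks[s + k][0]
                if k < len(fold) - 1:
                    if raw.casefold() != nt:
                        ok = False
                        break
                else:
                    stripped = raw.rstrip(_TERMINAL_PUNCT)
                    if raw.casefold() == nt:
                        end_off = toks[s + k][2]
                    elif stripped.casefold() == nt:
                        end_off = toks[s + k][2] - (len(raw) - len(stripped))
                    else:
                        ok = False
            if ok and end_off is not None:
                candidates.setdefault(s, []).append((len(fold), end_off))
    spans: list[tuple[int, int]] = []
    i = 0
    while i < len(toks):
        if i in candidates:
            length, end = max(candidates[i])
            spans.append((toks[i][1], end))
            i += length
        else:
            i += 1
    return spans


def random_index(seed: int, n_names: int) -> NameIndex:
    """A synthetic index of roughly ``n_names`` scientific names."""
    per_genus = 8
    taxonomy = generate_taxonomy(
        seed=seed,
        n_genera=max(1, n_names // per_genus),
        species_per_genus=per_genus - 1,
        infraspecific_fraction=0.15,
        vernacular_fraction=0.05,
    )
    return build_index(taxonomy.records)


def perturbed_queries(index: NameIndex, rng: random.Random, n: int) -> list[str]:
    """Queries biased toward near-misses of indexed names."""
    from phytonym.benchmark import CorruptionSpec, perturb_name

    names = sorted({r.scientificName for r in index.records if not r.isVernacular})
    letters = "abcdefghijklmnopqrstuvwxyz"
    queries = []
    for _ in range(n):
        kind = rng.random()
        name = rng.choice(names)
        if kind < 0.35:
            k = rng.choice((1, 2))
            queries.append(
                perturb_name(name, CorruptionSpec(k, "substitution", rng.randrange(2**31))).text
            )
        elif kind < 0.6:
            k = rng.choice((1, 2, 3))
            queries.append(
                perturb_name(name, CorruptionSpec(k, "mixed", rng.randrange(2**31))).text
            )
        elif kind < 0.75:
            queries.append(name)
        else:
            queries.append(
                " ".join(
                    "".join(rng.choice(letters) for _ in range(rng.randint(2, 10)))
                    for _ in range(rng.randint(1, 3))
                ).capitalize()
            )
    return queries


@pytest.fixture(scope="session")
def taxonomy():
    """Default synthetic backbone (1000 binomials, two datasets)."""
    return generate_taxonomy(seed=42)


@pytest.fixture(scope="session")
def backbone_index(taxonomy):
    return build_index(taxonomy.records)


@pytest.fixture()
def camellia_index():
    """The genus/epithet-valid-but-combination-absent fixture."""
    records = [
        SummaryRecord(1, "t1", "COL", "Camellia", taxonRank="genus",
                      taxonomicStatus="accepted"),
        SummaryRecord(2, "t2", "COL", "Camellia sinensis", taxonRank="species",
                      taxonomicStatus="accepted",
                      scientificNameAuthorship="(L.) Kuntze"),
        SummaryRecord(3, "t3", "COL", "Thea henryi", taxonRank="species",
                      taxonomicStatus="accepted"),
        SummaryRecord(4, "t4", "WFO", "Acer palmatum", taxonRank="species",
                      taxonomicStatus="accepted",
                      scientificNameAuthorship="Thunb."),
        SummaryRecord(5, "t5", "COL", "Tea plant", acceptedNameUsageID="t2",
                      isVernacular=True),
    ]
    return build_index(records)
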