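"""Synthetic backbone generation and the name-corruption benchmark.

The generator builds a reproducible multi-dataset backbone — genera,
binomials, infraspecific names with rank markers, author citations with
years, synonym → accepted links, vernacular names and cross-dataset
duplicates — from pronounceable Latin-like syllables, so the whole
toolkit is exercisable without downloading any source dataset.  Same
parameters + seed ⇒ byte-identical output.

The benchmark protocol mirrors the recall experiment the matcher is
built for: draw test names from an indexed backbone, corrupt each word
by a fixed number of character edits (substitutions by default, never
touching spaces, so word structure is preserved), run the matching
cascade, and count names recalled — status ``Match`` or ``Recorrect``.
A parallel parse benchmark counts names by parse outcome.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, ToolkitConfig
from .distance import levenshtein
from .matcher import match_batch
from .nameindex import DWC_COLUMNS, NameIndex, SummaryRecord
from .parser import ParsedName, parse_name

_SYLLABLES = (
    "ba", "ca", "da", "fa", "ga", "la", "ma", "na", "pa", "ra", "sa", "ta",
    "be", "ce", "de", "fe", "ge", "le", "me", "ne", "pe", "re", "se", "te",
    "bi", "ci", "di", "fi", "gi", "li", "mi", "ni", "pi", "ri", "si", "ti",
    "bo", "co", "do", "fo", "go", "lo", "mo", "no", "po", "ro", "so", "to",
    "bu", "cu", "du", "fu", "gu", "lu", "mu", "nu", "pu", "ru", "su", "tu",
)
_GENUS_ENDINGS = ("us", "a", "um", "ia", "ella", "opsis", "anthus", "aria")
_EPITHET_ENDINGS = ("us", "a", "um", "ensis", "iana", "ifolia", "icola", "oides")
_AUTHOR_POOL = (
    "L.", "Mill.", "Thunb.", "DC.", "Benth.", "Hook. f.", "Franch.",
    "Maxim.", "Diels", "A. Gray", "Sm.", "Willd.", "(L.) Kuntze",
    "(Thunb.) Siebold & Zucc.", "Baker", "Hance",
)
_RANK_MARKERS = ("var.", "subsp.", "f.")
_MARKER_RANK = {"var.": "variety", "subsp.": "subspecies", "f.": "form"}
_VERN_ADJ = ("red", "white", "mountain", "dwarf", "creeping", "giant", "silver", "marsh")
_VERN_NOUN = ("maple", "pine", "lily", "fern", "orchid", "grass", "willow", "thorn")


@dataclass
class GeneratorParams:
    """Defaults describe a desk-scale two-dataset backbone of 1000 binomials."""

    n_genera: int = 40
    species_per_genus: int = 25
    infraspecific_fraction: float = 0.10
    synonym_fraction: float = 0.20
    vernacular_fraction: float = 0.10
    authorship_fraction: float = 0.80
    year_fraction: float = 0.30
    hybrid_fraction: float = 0.02
    duplicate_fraction: float = 0.05
    dataset_ids: tuple[str, ...] = ("COL", "WFO")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "infraspecific_fraction", "synonym_fraction", "vernacular_fraction",
            "authorship_fraction", "year_fraction", "hybrid_fraction",
            "duplicate_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genera < 0 or self.species_per_genus < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SyntheticTaxonomy:
    records: list[SummaryRecord]
    params: GeneratorParams

    def to_tsv(self, path: str | Path) -> None:
        """Write a DwC-style TSV ingestible by the name index."""
        lines = ["\t".join(DWC_COLUMNS)]
        for r in self.records:
            d = r.as_dict()
            d["isVernacular"] = "true" if r.isVernacular else "false"
            lines.append("\t".join(str(d[c]) for c in DWC_COLUMNS))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def binomials(self) -> list[str]:
        return [
            r.scientificName
            for r in self.records
            if r.taxonRank == "species" and not r.isVernacular
        ]

    def full_names(self) -> list[str]:
        """Scientific names with their author citation (and year) appended."""
        out = []
        for r in self.records:
            if r.isVernacular:
                continue
            name = r.scientificName
            if r.scientificNameAuthorship:
                name += " " + r.scientificNameAuthorship
                if r.namePublishedInYear:
                    name += " " + r.namePublishedInYear
            out.append(name)
        return out


def _unique_word(rng: random.Random, seen: set[str], endings: tuple[str, ...]) -> str:
    while True:
        w = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
        w += rng.choice(endings)
        if w not in seen:
            seen.add(w)
            return w


def generate_taxonomy(
    params: GeneratorParams | None = None, seed: int | None = None, **overrides
) -> SyntheticTaxonomy:
    """Build a reproducible synthetic backbone.

    ``seed`` and keyword overrides take precedence over ``params``.
    """
    p = params or GeneratorParams()
    if seed is not None:
        overrides["seed"] = seed
    if overrides:
        p = replace(p, **overrides)
    rng = random.Random(p.seed)
    records: list[SummaryRecord] = []
    rid = 1
    counters = {"G": 0, "S": 0, "I": 0, "V": 0, "D": 0}
    accepted_by_ds: dict[str, list[SummaryRecord]] = {ds: [] for ds in p.dataset_ids}
    genus_seen: set[str] = set()

    def tid(kind: str) -> str:
        counters[kind] += 1
        return f"{kind}{counters[kind]:06d}"

    def emit(**kwargs) -> SummaryRecord:
        nonlocal rid
        rec = SummaryRecord(recordID=rid, **kwargs)
        records.append(rec)
        rid += 1
        return rec

    n_datasets = max(1, len(p.dataset_ids))
    for gi in range(p.n_genera):
        ds = p.dataset_ids[gi % n_datasets] if p.dataset_ids else ""
        genus = _unique_word(rng, genus_seen, _GENUS_ENDINGS).capitalize()
        family = genus + "aceae"
        higher = f"Plantae|Tracheophyta|Magnoliopsida|{family}"
        genus_rec = emit(
            taxonID=tid("G"),
            datasetID=ds,
            scientificName=genus,
            taxonRank="genus",
            taxonomicStatus="accepted",
            higherClassification=higher if rng.random() < 0.5 else "",
        )
        epithet_seen: set[str] = set()
        for _si in range(p.species_per_genus):
            epithet = _unique_word(rng, epithet_seen, _EPITHET_ENDINGS)
            if rng.random() < p.hybrid_fraction:
                epithet = "×" + epithet
            binomial = f"{genus} {epithet}"
            authorship = (
                rng.choice(_AUTHOR_POOL)
                if rng.random() < p.authorship_fraction
                else ""
            )
            year = (
                str(rng.randint(1753, 2024))
                if authorship and rng.random() < p.year_fraction
                else ""
            )
            accepted_here = accepted_by_ds.setdefault(ds, [])
            is_syn = rng.random() < p.synonym_fraction and bool(accepted_here)
            sp = emit(
                taxonID=tid("S"),
                datasetID=ds,
                scientificName=binomial,
                scientificNameAuthorship=authorship,
                taxonRank="species",
                taxonomicStatus="synonym" if is_syn else "accepted",
                acceptedNameUsageID=(
                    rng.choice(accepted_here).taxonID if is_syn else ""
                ),
                parentNameUsageID=genus_rec.taxonID,
                namePublishedInYear=year,
                higherClassification=genus_rec.higherClassification,
            )
            if not is_syn:
                accepted_here.append(sp)
                if rng.random() < p.infraspecific_fraction:
                    marker = rng.choice(_RANK_MARKERS)
                    infra = _unique_word(rng, epithet_seen, _EPITHET_ENDINGS)
                    emit(
                        taxonID=tid("I"),
                        datasetID=ds,
                        scientificName=f"{binomial} {marker} {infra}",
                        scientificNameAuthorship=(
                            rng.choice(_AUTHOR_POOL)
                            if rng.random() < p.authorship_fraction
                            else ""
                        ),
                        taxonRank=_MARKER_RANK[marker],
                        taxonomicStatus="accepted",
                        parentNameUsageID=sp.taxonID,
                        higherClassification=genus_rec.higherClassification,
                    )
                if rng.random() < p.vernacular_fraction:
                    emit(
                        taxonID=tid("V"),
                        datasetID=ds,
                        scientificName=(
                            rng.choice(_VERN_ADJ).capitalize()
                            + " "
                            + rng.choice(_VERN_NOUN)
                        ),
                        acceptedNameUsageID=sp.taxonID,
                        isVernacular=True,
                    )
            if n_datasets > 1 and rng.random() < p.duplicate_fraction:
                other = p.dataset_ids[(gi + 1) % n_datasets]
                emit(
                    taxonID=tid("D"),
                    datasetID=other,
                    scientificName=binomial,
                    scientificNameAuthorship=authorship,
                    taxonRank="species",
                    taxonomicStatus="accepted",
                    namePublishedInYear=year,
                )
    return SyntheticTaxonomy(records=records, params=p)


# ---------------------------------------------------------------------------
# corruption


@dataclass
class CorruptionSpec:
    """How to corrupt a name: ``edits_per_word`` character edits in every
    whitespace-delimited word, substitutions by default."""

    edits_per_word: int = 1
    edit_kind: str = "substitution"  # or "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edits_per_word < 0:
            raise ValueError("edits_per_word must be >= 0")
        if self.edit_kind not in ("substitution", "mixed"):
            raise ValueError(f"unknown edit_kind: {self.edit_kind!r}")


@dataclass
class PerturbedName:
    text: str
    shortfall: int = 0  # requested edits that could not be applied


def _substitute(rng: random.Random, word: str, k: int) -> tuple[str, int]:
    letters = [i for i, c in enumerate(word) if c.isalpha()]
    n = min(k, len(letters))
    chars = list(word)
    for i in rng.sample(letters, n):
        pool = string.ascii_uppercase if chars[i].isupper() else string.ascii_lowercase
        repl = rng.choice([c for c in pool if c != chars[i]])
        chars[i] = repl
    return "".join(chars), k - n


def _mixed(rng: random.Random, word: str, k: int) -> tuple[str, int]:
    out = word
    applied = 0
    for _ in range(k):
        if not out:
            break
        op = rng.choice(("sub", "ins", "del"))
        pos = rng.randrange(len(out))
        if op == "sub" and out[pos].isalpha():
            pool = string.ascii_uppercase if out[pos].isupper() else string.ascii_lowercase
            out = out[:pos] + rng.choice([c for c in pool if c != out[pos]]) + out[pos + 1:]
        elif op == "ins":
            out = out[:pos] + rng.choice(string.ascii_lowercase) + out[pos:]
        elif op == "del" and len(out) > 1:
            out = out[:pos] + out[pos + 1:]
        else:
            continue
        applied += 1
    return out, k - applied


def perturb_name(name: str, spec: CorruptionSpec) -> PerturbedName:
    """Corrupt every word of ``name`` by ``spec.edits_per_word`` edits.

    Spaces are never touched, so word structure is preserved.
    Substitutions replace a letter with a different letter of the same
    case; a word with fewer letters than requested edits receives as
    many as it can and the shortfall is recorded.  With substitutions
    and at most two edits the per-word edit distance equals the number
    of edits applied.
    """
    if not name:
        raise ValueError("cannot perturb an empty name")
    rng = random.Random(spec.seed)
    words = name.split(" ")
    out: list[str] = []
    shortfall = 0
    for word in words:
        if spec.edits_per_word == 0:
            out.append(word)
            continue
        fn = _substitute if spec.edit_kind == "substitution" else _mixed
        for _attempt in range(20):
            corrupted, short = fn(rng, word, spec.edits_per_word)
            applied = spec.edits_per_word - short
            if applied == 0 or (
                corrupted != word
                and levenshtein(corrupted, word, limit=spec.edits_per_word)
                <= spec.edits_per_word
            ):
                break
        out.append(corrupted)
        shortfall += short
    return PerturbedName(text=" ".join(out), shortfall=shortfall)


def build_test_sets(
    names: Sequence[str],
    n_per_category: int,
    seed: int = 0,
    skip_authorship: bool = False,
) -> dict[str, list[str]]:
    """The three benchmark categories: correct names, one edit per word,
    two edits per word (substitutions).

    With ``skip_authorship`` the citation (as detected by the parser) is
    left intact and only the name part is corrupted.
    """
    rng = random.Random(seed)
    pick = (
        (lambda: rng.sample(list(names), n_per_category))
        if n_per_category <= len(names)
        else (lambda: rng.choices(list(names), k=n_per_category))
    )
    sets: dict[str, list[str]] = {"correct": pick()}
    for key, k in (("oneChar", 1), ("twoChar", 2)):
        corrupted = []
        for name in pick():
            spec = CorruptionSpec(edits_per_word=k, seed=rng.randrange(2**31))
            if skip_authorship:
                parsed = parse_name(name)
                if parsed.scientificNameAuthorship:
                    head = perturb_name(parsed.scientificName, spec).text
                    tail = parsed.scientificNameAuthorship + (
                        " " + parsed.namePublishedInYear
                        if parsed.namePublishedInYear
                        else ""
                    )
                    corrupted.append(head + " " + tail)
                    continue
            corrupted.append(perturb_name(name, spec).text)
        sets[key] = corrupted
    return sets


# ---------------------------------------------------------------------------
# benchmark runners


@dataclass
class CategoryResult:
    category: str
    total: int
    matched: int
    recorrected: int
    vernacular: int
    unmatched: int

    @property
    def recalled(self) -> int:
        """Names recalled: exact or corrected hits (vernacular hits do not count)."""
        return self.matched + self.recorrected

    @property
    def recall_rate(self) -> float:
        return self.recalled / self.total if self.total else 0.0


@dataclass
class MatchBenchmarkReport:
    categories: list[CategoryResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": c.category,
                    "total": c.total,
                    "matched": c.matched,
                    "recorrected": c.recorrected,
                    "vernacular": c.vernacular,
                    "unmatched": c.unmatched,
                    "recalled": c.recalled,
                    "recall_rate": round(c.recall_rate, 4),
                }
                for c in self.categories
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def total_recalled(self) -> int:
        return sum(c.recalled for c in self.categories)

    @property
    def total_names(self) -> int:
        return sum(c.total for c in self.categories)


def run_match_benchmark(
    test_sets: dict[str, Sequence[str]],
    index: NameIndex,
    config: ToolkitConfig = DEFAULT_CONFIG,
) -> MatchBenchmarkReport:
    """Match every test name and tally recall per category."""
    categories = []
    for category, names in test_sets.items():
        tallies = {"Match": 0, "Recorrect": 0, "Vernacular": 0, "Unmatch": 0}
        names = list(names)
        for start in range(0, len(names), config.batch_limit):
            for res in match_batch(
                names[start : start + config.batch_limit], index, config=config
            ):
                tallies[res.status] += 1
        categories.append(
            CategoryResult(
                category=category,
                total=len(names),
                matched=tallies["Match"],
                recorrected=tallies["Recorrect"],
                vernacular=tallies["Vernacular"],
                unmatched=tallies["Unmatch"],
            )
        )
    return MatchBenchmarkReport(categories)


@dataclass
class ParseBenchmarkReport:
    total: int
    counts: dict[str, int]
    failures: list[str]
    partials: list[str]
    results: list[ParsedName] = field(default_factory=list)

    @property
    def resolved(self) -> int:
        return self.counts.get("parsed", 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"parseRemark": k, "count": v} for k, v in sorted(self.counts.items())]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_parse_benchmark(names: Sequence[str]) -> ParseBenchmarkReport:
    """Parse every name and tally outcomes; failures are listed verbatim."""
    counts: dict[str, int] = {}
    failures: list[str] = []
    partials: list[str] = []
    results: list[ParsedName] = []
    for name in names:
        parsed = parse_name(name)
        results.append(parsed)
        counts[parsed.parseRemark] = counts.get(parsed.parseRemark, 0) + 1
        if parsed.parseRemark == "unparsable":
            failures.append(name)
        elif parsed.parseRemark == "parsed_partial":
            partials.append(name)
    return ParseBenchmarkReport(
        total=len(names), counts=counts, failures=failures, partials=partials,
        results=results,
    )
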