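# phytonym

A plant-name resolution toolkit for biodiversity informatics: it
normalizes raw name strings, parses them into their nomenclatural parts,
matches misspelled names against an integrated multi-source name
backbone, finds whole scientific names inside free text, and serves
faceted retrieval over Darwin-Core-style taxon tables — as a Python
library, a command-line tool (`phytonym`) and a small JSON API.

It is aimed at botanists, ecologists and data curators who need to clean
species lists, reconcile occurrence data against backbone taxonomies
(Catalogue of Life, World Flora Online, POWO, GBIF Backbone, …), or
extract taxon mentions from survey reports.

## The method

**Normalization.** Every input is canonicalized first: Unicode
compatibility composition, a configurable special-character map
(typographic quotes/dashes → ASCII, `_x` hybrid markers → `×`), space
repair around periods and parentheses. The transform is idempotent and
case-preserving.

**Parsing.** A normalized name is decomposed by the rules of binomial
nomenclature into *genusOrAbove*, *specificEpithet*, an optional rank
marker (`var.`, `subsp.`, `f.`, …) with its *infraspecificEpithet*, the
author citation, and the publication year (the last standalone 4-digit
token in [1700, now] inside the citation). `f.` is a rank marker only
when followed by a lowercase epithet; otherwise it is the *filius*
author abbreviation.

**Matching.** A cascade that stops at the first stage with hits:

```
exact  →  vernacular-exact  →  fuzzy d=1  →  fuzzy d=2
      →  (strip author citation, repeat exact → fuzzy1 → fuzzy2)  →  Unmatch
```

Fuzzy lookup is per token: a query hits an indexed name when both have
the same number of words and every aligned word pair is within
Levenshtein distance *d* (one more, one less, or one different
character per edit). Candidates carry a similarity coefficient

```
sim(a, b) = 1 − Lev(a, b) / max(|a|, |b|)
```

on case-folded whole strings and are returned in descending similarity
order. Statuses follow the usual reconciliation vocabulary: `Match`
(distance 0), `Recorrect` (fuzzy hit, with the suggested correction),
`Vernacular`, `Unmatch`. Candidate generation uses symmetric-delete
variant hashing and is provably complete for *d* ≤ 2; the test suite
verifies it against a brute-force scan with an independent alignment
library.

**Finding names in text.** The scanner opens a candidate at every token
starting with an uppercase letter or `×`, extends it greedily while a
token-prefix trie still contains indexed names beginning with the
phrase, then backtracks to the longest *complete* indexed name. That
last step matters: a genus word and an epithet word that are each valid
in other names are **not** reported as a binomial unless the combination
itself is indexed ("Camellia henryi" stays unreported while "Camellia"
and "Thea henryi" are both indexed). Matches come with 0-based,
half-open character offsets.

**Retrieval.** Token-prefix search with conjunctive filters (year, rank,
status, dataset, vernacular opt-in), results sorted by name length, and
facet counts per dimension that always sum to the total hit count.

## Worked example

```python
from phytonym import build_index, match_name, find_names, parse_name
from phytonym.nameindex import SummaryRecord

records = [
    SummaryRecord(1, "wfo-001", "WFO", "Camellia", taxonRank="genus",
                  taxonomicStatus="accepted"),
    SummaryRecord(2, "wfo-002", "WFO", "Camellia sinensis",
                  scientificNameAuthorship="(L.) Kuntze",
                  taxonRank="species", taxonomicStatus="accepted"),
    SummaryRecord(3, "col-117", "COL", "Thea henryi",
                  taxonRank="species", taxonomicStatus="accepted"),
]
index = build_index(records)

res = match_name("Camellia sinencis", index)
print(res.status, res.stage_used)           # Recorrect fuzzy1
best = res.best
print(best.record.scientificName, best.record.datasetID,
      round(best.similarity, 4), best.total_distance)
                                            # Camellia sinensis WFO 0.9412 1

for m in find_names("We sampled Camellia henryi and Camellia sinensis.", index):
    print(m.startIndex, m.endIndex, m.scientificName, m.taxonRank)
# 11 19 Camellia genus          <- "Camellia henryi" is not an indexed binomial
# 31 48 Camellia sinensis species

p = parse_name("Poa annua var. annua L. 1753")
print(p.genusOrAbove, p.specificEpithet, p.rankMarker, p.infraspecificEpithet,
      p.scientificNameAuthorship, p.namePublishedInYear)
# Poa annua var. annua L. 1753
```

The misspelled "Camellia sinencis" is corrected at the first fuzzy stage
(one substitution in the epithet, similarity 1 − 1/17 ≈ 0.9412); the
text scan reports character offsets you can slice the source text with.

The same operations are available from the shell:

```sh
phytonym --db names.sqlite ingest backbone.tsv --dataset WFO
phytonym --db names.sqlite match names.csv --out report.csv
phytonym --db names.sqlite find fieldnotes.txt --html highlighted.html
phytonym --db names.sqlite serve --port 8440    # POST /Api/{Retrieval,Match,Search,Parse,Detail}
```

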