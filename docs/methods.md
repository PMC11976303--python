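# Methods

This note records the model behind each component, the tunables and
their defaults, what the synthetic backbone does and does not emulate,
and the design choices made where more than one reading was defensible.

## Normalization

Pipeline, in order: NFKC composition → special-character map → insert a
space after each retain-space character (`.` and `)`) → collapse
whitespace runs and trim → drop the space before `)` and `,` and after
`(` → rewrite token-initial `_x`/`_X` to the canonical hybrid sign `×`.

The special-character map ships as a two-column text file
(`data/charmap.tsv`, codepoint → replacement) so deployments can extend
it; it covers typographic quotes, primes, the dash family and exotic
spaces. NFKC already folds fullwidth ASCII forms. The map is
deliberately conservative: a bare `x`/`X` between tokens is *not*
rewritten to `×`, because "x" is also a legitimate author initial and a
common OCR artifact; only the unambiguous `_x` marker is rewritten.

Consequences worth knowing:

* the transform is idempotent (property-tested over arbitrary Unicode);
* letter case and diacritics are preserved — case handling belongs to
  the matcher's case-folded comparisons, and spelling repair to the
  fuzzy cascade;
* length can grow only by the mandated insertions after periods and
  closing parentheses;
* a period may legitimately be followed by `)` or `,` (as in `(L.)`),
  not only by a space.

## Parsing

The name grammar is: capitalized (or `×`-prefixed) genus token, then at
most one lowercase specific epithet, then optionally a rank marker from
{`var.`, `subsp.`, `ssp.`, `subvar.`, `subf.`, `cv.`, `f.`} followed by
a lowercase infraspecific epithet; a bare second lowercase token is
accepted as a markerless trinomial. The author citation starts at the
first token that is capitalized, parenthesized, or period-bearing —
standard nomenclatural convention, centralized in one predicate.
`f.` is a rank marker only when a lowercase token follows; otherwise it
is the *filius* abbreviation and belongs to the citation.

The year is the last standalone 4-digit token of the citation within
[1700, current year], optionally parenthesized. The 1700 floor keeps
collection numbers, page numbers and herbarium codes out of the year
slot; botanical publication predating 1700 is not citable by year under
the starting-point conventions anyway.

Outcomes: `parsed`, `parsed_partial` (the name part parsed but a
trailing tail fits neither grammar; the tail is preserved verbatim in
`parseRemarkDetail`), `unparsable` (empty or not name-shaped). The
parser is total — property-tested never to raise — and reassembling the
epithet slots always reproduces `scientificName` exactly.

## Index and fuzzy semantics

The central interpretive decision of the toolkit: "differs by *d*
characters" is applied **per token**, not to the concatenated string. A
query hits an indexed name when both split into the same number of
space-separated tokens and every aligned token pair is within
Levenshtein distance *d* ∈ {1, 2}. This is the semantics under which
corrupting *every word* of a name by one character still yields
guaranteed recall at d = 1 — which is exactly the benchmark the matcher
is designed around. A whole-string mode (single *d*-edit budget for the
entire name) is available behind `fuzzy_mode = whole_string` for
comparison; it is strictly stricter on multi-word names.

Token alignment requires equal token counts; no merges or splits across
spaces. This keeps the contract brute-force-checkable, and the
authorship-stripping stage of the cascade compensates for the most
common token-count mismatch in practice (a citation appended to the
query but not stored in the canonical name).

Candidate generation is symmetric-delete hashing: each vocabulary token
(per token-count bucket, per position) is indexed under all variants
reachable by deleting up to two characters; a query token's own deletion
variants then point to a small candidate set which a bounded
dynamic-programming Levenshtein verifies. If `Lev(a, b) ≤ d`, the two
strings always share a variant reachable by at most *d* deletions from
each side, so the method is complete; the test suite nevertheless
checks exact set equality against a brute-force per-token scan using an
independent alignment library (edlib), over thousands of seeded queries.

Exact lookup case-folds the whole string. The token-prefix trie is
case-sensitive on the genus initial (the writing convention the text
scanner relies on) and case-folded elsewhere, and counts distinct names
rather than records. Vernacular records are reachable through exact
lookup only — there is no fuzzy or prefix matching over vernacular
strings, because no correction rule is defined for them.

Records persist in a single-table SQLite store keyed by `recordID`;
index structures are rebuilt on load. Rebuilding a desk-scale index
(10⁴–10⁵ names) takes well under a second, which we prefer over
serializing the trie and variant tables.

## Matching cascade

Stage order: exact → vernacular-exact → fuzzy d=1 → fuzzy d=2 → if the
parser detects an author citation, strip it and repeat exact → fuzzy1 →
fuzzy2 on the name part. The first stage with surviving candidates
terminates the cascade. A dataset filter is applied to the candidates
of each stage, not to the cascade structure itself — so a stage whose
hits are all filtered away counts as empty and the cascade continues.

Similarity is `1 − Lev/max(len)` on case-folded whole strings — the
standard normalized edit similarity; it is 1 exactly on a distance-0
match, making the `Match`/`Recorrect` boundary coincide with similarity
1. Ties at equal similarity break by ascending name length, then name,
then configured dataset priority (registry order in
`data/datasets.tsv`), then record ID, so output is fully deterministic.

The vernacular check sits immediately after the scientific exact match
and is exact-only. Batch submissions are capped at 1000 names
(`batch_limit`), matching the documented submission limit of the online
service this toolkit models.

## Text scanning

The literal greedy rule — "emit the last phrase that is still a viable
prefix" — can emit a phrase that is a prefix of indexed names but not a
complete name itself. This implementation instead backtracks to the
longest accumulated prefix that is a *complete* indexed name, because
whole-name validity is the point of index-backed scanning: combinations
absent from the backbone must not be reported even when each word is
individually valid. This is the single most consequential interpretive
decision in the package, and the equivalence oracle in the tests (slide
every indexed name over every position, keep leftmost-longest
non-overlapping occurrences) pins its semantics exactly.

Details: tokens are maximal runs of letters, hyphen, period, apostrophe
and `×`; sentence-terminal punctuation is stripped only from the final
token of a candidate and excluded from the emitted span, so internal
rank-marker periods survive; offsets are 0-based half-open character
positions, and re-slicing the text at them reproduces the emitted name
up to normalization. Sentence-initial capitalized ordinary words simply
fail the first prefix probe and cost one trie query. Genus-only matches
are emitted by default; `finder_min_tokens = 2` suppresses them.

## Retrieval

Browse-style token-prefix containment (every query token must prefix
some name token, case-folded), *not* edit distance — correction belongs
to the matcher. Filters are conjunctive; records lacking a year drop
out while a year filter is active; vernacular records require opt-in.
Hits sort by (name length, name, record ID) ascending, facet counts are
computed over the full filtered hit set (so each dimension sums to
`totalHits`), and pagination slices the sorted list. An empty query
with no filters returns an empty page rather than a full dump.

## Synthetic backbone

The generator emulates the structural features the toolkit's contracts
depend on: multi-dataset provenance, genus/species/infraspecific ranks,
author citations with years, synonym→accepted links within a dataset,
vernacular aliases, hybrid-sign names and cross-dataset duplicate names.
Defaults — 40 genera × 25 species (1000 binomials) across two datasets,
infraspecific 0.10, synonym 0.20, vernacular 0.10, authorship 0.80,
year-in-citation 0.30, hybrid 0.02, duplicate 0.05 — are sized so a
default build exercises every cascade stage while indexing in well
under a second; the fractions are in the range observed in real
backbone slices (synonymy around 20–40%, infraspecifics around 10%).

What it does **not** emulate: the crowding of an 8-million-name
production index, where many real names sit within one or two edits of
each other. On a desk-scale synthetic backbone nearly every corrupted
name has a unique nearest neighbour, so corruption-recall benchmarks
here measure the *mechanism* (per-token distance cascade) and come out
at or near 100%; published recall figures from production-scale systems
reflect index density and a possibly different distance semantic, and
are not reproducible from synthetic data. It also does not emulate
OCR-style damage (split/joined words), author-name variability beyond a
fixed pool, or non-Latin vernacular scripts.

Name corruption follows the per-word protocol: every
whitespace-delimited word receives exactly `edits_per_word`
substitutions at distinct letter positions (same-case replacement
letters, never spaces, digits or punctuation), so for at most two edits
the per-word Levenshtein distance provably equals the number of edits
applied — verified against the edlib oracle over thousands of draws.
Words with fewer letters than requested edits take what they can and
the shortfall is recorded. A mixed substitution/insertion/deletion mode
exists for stress tests; author citations are corrupted too by default
(`skip_authorship` turns that off).

## Numerical and degenerate-input choices

* Levenshtein is a two-row DP with length pruning and row-minimum early
  abandon; `limit + 1` is the over-budget sentinel.
* Similarity of two empty strings is 1 (they are equal); empty vs
  non-empty is 0.
* Blank input after normalization: matcher returns `Unmatch`, parser
  returns `unparsable`, finder returns no matches — never an exception.
* Fuzzy distance is validated to {1, 2}; the symmetric-delete tables are
  built once per index at depth 2 and serve both distances.
* `detail` resolves accepted links within the same dataset only, walks
  parent chains with a visited set (cycle-safe), and reports dangling
  links as a warning field instead of failing.

## Problem sizes in the checked-in runs

The test suite's oracle sweeps use 20 random indexes of 60–1000 names
with 200 queries each for fuzzy equivalence, six indexes up to 500
names with generated texts for finder equivalence, 1000 corrupted
binomials for the recall property, and ≥1000 names for the parser
round trip. The acceptance script runs the three-category matching
benchmark at 2000 names per category against a 2000-binomial backbone
and the parse benchmark at 6000 names. These sizes keep a full check
under a minute on one CPU while leaving every contract at or above the
scale its statement requires.

## Known limitations

* Authorship detection is heuristic; lowercase-particle author names
  ("van der …") are mistaken for epithets until the next capitalized
  token.
* No cross-rank promotion: a binomial query never matches its genus
  record.
* No abbreviation expansion in text scanning ("C. sinensis" is not
  linked to "Camellia sinensis").
* Fuzzy matching cannot recover names whose corruption changes the
  token count, or whose rank marker is corrupted into an
  authorship-looking token and whose binomial parent is absent.
* The JSON service is a development server: no authentication, no rate
  limiting, single process.
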