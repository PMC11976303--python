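"""Finding whole scientific names in free text.

The scanner walks the text token by token.  A token opening with an
uppercase letter or the hybrid sign ``×`` starts a candidate phrase; the
phrase is extended greedily while the index still contains names
beginning with it (a token-prefix count query), and on termination the
longest *complete* indexed name among the accumulated prefixes is
emitted with its character offsets.  Backtracking to a complete name —
rather than emitting the last prefix-viable phrase — is what rejects
plausible-looking but unindexed combinations: a genus word and an
epithet word that are each valid somewhere must still co-occur as an
indexed name to be reported.

Matches are non-overlapping, leftmost-longest; scanning resumes after
each emitted match.  Offsets are 0-based, half-open, in characters, and
re-slicing the text at them reproduces the reported name up to
normalization.  Terminal sentence punctuation on the final token is
stripped before lookup and excluded from the match span; punctuation
internal to a name (rank-marker and author periods) is kept.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field
from typing import Sequence

from .nameindex import NameIndex
from .normalize import normalize_name

# Maximal runs of letters, hyphen, period, apostrophe, or the hybrid sign.
_TOKEN = re.compile(r"(?:[^\W\d_]|[×.'’-])+")

_TERMINAL_PUNCT = ".,;:!?"


@dataclass
class TextMatch:
    scientificName: str
    startIndex: int
    endIndex: int
    taxonRank: str = ""
    taxonomicStatus: str = ""
    recordIDs: list[int] = field(default_factory=list)

    def as_dict(self) -> dict[str, object]:
        return {
            "scientificName": self.scientificName,
            "startIndex": self.startIndex,
            "endIndex": self.endIndex,
            "taxonRank": self.taxonRank,
            "taxonomicStatus": self.taxonomicStatus,
            "recordIDs": list(self.recordIDs),
        }


def tokenize_text(text: str) -> list[tuple[str, int, int]]:
    """Tokens with (token, start, end) character offsets.

    >>> tokenize_text("a  b")
    [('a', 0, 1), ('b', 3, 4)]
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN.finditer(text)]


def _opens_name(token: str) -> bool:
    c = token[0]
    return c.isupper() or c == "×"


def _best_record(index: NameIndex, ids: Sequence[int]):
    """Deterministic representative record: accepted status first, then
    lowest record ID."""
    recs = [index.records_by_id[i] for i in ids]
    recs.sort(key=lambda r: (r.taxonomicStatus.casefold() != "accepted", r.recordID))
    return recs[0]


def find_names(
    text: str,
    index: NameIndex,
    min_tokens: int = 1,
) -> list[TextMatch]:
    """All whole indexed names occurring in ``text``, with offsets.

    ``min_tokens`` filters out short matches (set 2 to suppress
    genus-only hits).
    """
    toks = tokenize_text(text)
    matches: list[TextMatch] = []
    i = 0
    n = len(toks)
    while i < n:
        if not _opens_name(toks[i][0]):
            i += 1
            continue
        phrase: list[str] = []  # raw tokens accepted so far
        best: tuple[int, str, int, list[int]] | None = None
        j = i
        while j < n:
            raw, _s, e = toks[j]
            stripped = raw.rstrip(_TERMINAL_PUNCT)
            # completeness: could the phrase ending at token j be a full name?
            if j - i + 1 >= min_tokens:
                for form, end_off in ((raw, e), (stripped, e - (len(raw) - len(stripped)))):
                    if not form:
                        continue
                    ids = index.lookup_exact(" ".join(phrase + [form]))
                    ids = [
                        rid
                        for rid in ids
                        if not index.records_by_id[rid].isVernacular
                    ]
                    if ids:
                        best = (j, " ".join(phrase + [form]), end_off, ids)
                        break
            # viability: do indexed names continue beyond this phrase?
            if index.phrase_prefix_count(phrase + [raw]) > 0:
                phrase.append(raw)
                j += 1
                continue
            break
        if best is not None:
            j_end, _name, end_off, ids = best
            start = toks[i][1]
            rec = _best_record(index, ids)
            matches.append(
                TextMatch(
                    scientificName=normalize_name(text[start:end_off]),
                    startIndex=start,
                    endIndex=end_off,
                    taxonRank=rec.taxonRank,
                    taxonomicStatus=rec.taxonomicStatus,
                    recordIDs=list(ids),
                )
            )
            i = j_end + 1
        else:
            i += 1
    return matches


def render_html(text: str, matches: Sequence[TextMatch]) -> str:
    """Render the text with found names wrapped in highlight markup.

    A portable stand-in for highlighted word-processor output: each match
    becomes ``<mark class="taxon">…</mark>`` inside a ``<pre>`` block.
    """
    parts: list[str] = ['<pre class="phytonym-text">']
    pos = 0
    for m in sorted(matches, key=lambda m: m.startIndex):
        parts.append(_html.escape(text[pos:m.startIndex]))
        parts.append(
            '<mark class="taxon">%s</mark>'
            % _html.escape(text[m.startIndex:m.endIndex])
        )
        pos = m.endIndex
    parts.append(_html.escape(text[pos:]))
    parts.append("</pre>")
    return "".join(parts)
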