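"""Nomenclatural parsing of plant-name strings.

A normalized name string is decomposed into its binomial-nomenclature
parts: ``genusOrAbove``, ``specificEpithet``, an optional rank marker and
``infraspecificEpithet``, the author citation, and the publication year
embedded in the citation.  A single word is a genus-or-above name; with
more words the leading capitalized (or hybrid-sign-prefixed) token is the
genus, following lowercase tokens fill the epithet slots, and the
authorship begins at the first token that is capitalized, parenthesized,
or an author abbreviation carrying a period.

The classic ``f.`` ambiguity is resolved explicitly: ``f.`` is a rank
marker (forma) only when the next token is a lowercase epithet; otherwise
it is the author abbreviation for *filius*.

Parsing is total: it never raises, and inputs that do not look like a
name at all come back with ``parseRemark == "unparsable"``.  Trailing
tokens that fit neither the name grammar nor the authorship grammar
produce ``parsed_partial`` with the unconsumed tail preserved in
``parseRemarkDetail``.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field

from .normalize import normalize_name

#: Infraspecific rank markers recognized in name strings.  ``f.`` is
#: conditional (see module docstring).
RANK_MARKERS = ("var.", "subsp.", "ssp.", "subvar.", "subf.", "cv.", "f.")

#: Earliest accepted publication year (Linnaean-era floor keeps collection
#: numbers and page numbers out of the year slot).
YEAR_FLOOR = 1700

HYBRID_SIGN = "×"

_YEAR_TOKEN = re.compile(r"[(\[]?(\d{4})[)\],.;]*\Z")


@dataclass
class ParsedName:
    """Decomposition of one name string."""

    verbatim: str = ""
    scientificName: str = ""
    genusOrAbove: str = ""
    specificEpithet: str = ""
    rankMarker: str = ""
    infraspecificEpithet: str = ""
    scientificNameAuthorship: str = ""
    namePublishedInYear: str = ""
    parseRemark: str = "unparsable"
    parseRemarkDetail: str = ""

    def as_dict(self) -> dict[str, str]:
        return {
            "parseRemark": self.parseRemark,
            "scientificName": self.scientificName,
            "genusOrAbove": self.genusOrAbove,
            "specificEpithet": self.specificEpithet,
            "rankMarker": self.rankMarker,
            "infraspecificEpithet": self.infraspecificEpithet,
            "scientificNameAuthorship": self.scientificNameAuthorship,
            "namePublishedInYear": self.namePublishedInYear,
        }


def _is_lower_epithet(tok: str) -> bool:
    """Lowercase epithet token, optionally hybrid-prefixed, hyphens and
    apostrophes allowed, no digits or periods."""
    core = tok[1:] if tok.startswith(HYBRID_SIGN) else tok
    if not core or not core[0].isalpha() or not core[0].islower():
        return False
    return all((c.isalpha() and c.islower()) or c in "-'" for c in core)


def _is_capitalized(tok: str) -> bool:
    if not tok:
        return False
    if tok.startswith(HYBRID_SIGN):
        return len(tok) > 1 and tok[1].isupper()
    return tok[0].isupper()


def _starts_authorship(tok: str) -> bool:
    """First token of an author citation: capitalized, parenthesized, or a
    period-bearing abbreviation (covers lowercase ``f.``, ``auct.`` …)."""
    return tok.startswith("(") or _is_capitalized(tok) or "." in tok


def split_authorship_year(authorship: str) -> tuple[str, str]:
    """Split an author citation into (author, year).

    The year is the last standalone 4-digit token within
    [1700, current year], possibly wrapped in parentheses or trailed by
    punctuation; absent that, the year is empty and the citation is
    returned with normalized spacing.

    >>> split_authorship_year("(Thunb.) Siebold & Zucc. 1845")
    ('(Thunb.) Siebold & Zucc.', '1845')
    """
    toks = authorship.split()
    this_year = datetime.date.today().year
    year = ""
    idx: int | None = None
    for k in range(len(toks) - 1, -1, -1):
        m = _YEAR_TOKEN.fullmatch(toks[k])
        if m and YEAR_FLOOR <= int(m.group(1)) <= this_year:
            year = m.group(1)
            idx = k
            break
    if idx is not None:
        toks = toks[:idx] + toks[idx + 1:]
    author = " ".join(toks).strip(" ,")
    return author, year


def _merge_hybrid_sign(tokens: list[str]) -> list[str]:
    """Attach a standalone ``×`` token to the token that follows it."""
    out: list[str] = []
    k = 0
    while k < len(tokens):
        if tokens[k] == HYBRID_SIGN and k + 1 < len(tokens):
            out.append(HYBRID_SIGN + tokens[k + 1])
            k += 2
        else:
            out.append(tokens[k])
            k += 1
    return out


def parse_name(name: str) -> ParsedName:
    """Parse one name string into its nomenclatural parts.

    ``name`` is expected to be normalized already; normalization is
    applied defensively (it is idempotent).  Never raises.
    """
    verbatim = normalize_name(name)
    result = ParsedName(verbatim=verbatim)
    if not verbatim:
        result.parseRemarkDetail = "empty input"
        return result
    tokens = _merge_hybrid_sign(verbatim.split(" "))
    if not _is_capitalized(tokens[0]):
        result.parseRemarkDetail = (
            "name must begin with a capitalized word or the hybrid sign"
        )
        return result

    genus = tokens[0]
    specific = infra = rank = ""
    i = 1
    while i < len(tokens):
        tok = tokens[i]
        nxt = tokens[i + 1] if i + 1 < len(tokens) else None
        if tok in RANK_MARKERS:
            marker_ok = specific and not infra and not rank
            follower_ok = nxt is not None and _is_lower_epithet(nxt)
            if marker_ok and follower_ok:
                rank, infra = tok, nxt
                i += 2
                continue
            if tok == "f." and not follower_ok:
                break  # filius: authorship starts here
            break  # marker without a usable epithet: tail / authorship
        if _is_lower_epithet(tok):
            if not specific:
                specific = tok
            elif not infra and not rank:
                infra = tok  # trinomial without an explicit marker
            else:
                break  # no slot left
            i += 1
            continue
        break  # authorship or junk
    rest = tokens[i:]

    authorship = year = ""
    remark, detail = "parsed", ""
    if rest:
        if _starts_authorship(rest[0]):
            authorship, year = split_authorship_year(" ".join(rest))
        else:
            remark = "parsed_partial"
            detail = "unconsumed tail: " + " ".join(rest)

    parts = [genus]
    if specific:
        parts.append(specific)
    if rank:
        parts.append(rank)
    if infra:
        parts.append(infra)
    result.scientificName = " ".join(parts)
    result.genusOrAbove = genus
    result.specificEpithet = specific
    result.rankMarker = rank
    result.infraspecificEpithet = infra
    result.scientificNameAuthorship = authorship
    result.namePublishedInYear = year
    result.parseRemark = remark
    result.parseRemarkDetail = detail
    return result
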