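"""Bounded Levenshtein edit distance.

The fuzzy stages of the matching cascade are defined directly in terms of
Levenshtein distance ("one more character, one less character or one
different character"), so the primitive lives here rather than behind a
third-party wrapper.  ``levenshtein`` is a plain two-row dynamic programme
with an optional cutoff: once every cell of a row exceeds ``limit`` the
true distance cannot come back under it, and ``limit + 1`` is returned as
a sentinel.
"""

from __future__ import annotations


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Edit distance between ``a`` and ``b``.

    With ``limit`` set, returns ``limit + 1`` as soon as the distance is
    known to exceed ``limit`` (length pruning or row-minimum abandon).
    Comparison is on raw code points; callers case-fold first if they want
    case-insensitive semantics.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if limit is not None and abs(la - lb) > limit:
        return limit + 1
    if la == 0:
        return lb
    if lb == 0:
        return la
    if la > lb:  # iterate over the shorter string's row
        a, b, la, lb = b, a, lb, la
    prev = list(range(la + 1))
    cur = [0] * (la + 1)
    for j in range(1, lb + 1):
        cur[0] = j
        cb = b[j - 1]
        row_min = j
        for i in range(1, la + 1):
            cost = 0 if a[i - 1] == cb else 1
            v = min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + cost)
            cur[i] = v
            if v < row_min:
                row_min = v
        if limit is not None and row_min > limit:
            return limit + 1
        prev, cur = cur, prev
    d = prev[la]
    if limit is not None and d > limit:
        return limit + 1
    return d


def deletion_variants(token: str, max_deletions: int) -> set[str]:
    """All strings obtainable from ``token`` by deleting up to
    ``max_deletions`` characters (including ``token`` itself).

    Used for symmetric-delete candidate generation: if
    ``levenshtein(a, b) <= d`` then ``a`` and ``b`` share at least one
    variant reachable with at most ``d`` deletions from each side.
    """
    out = {token}
    frontier = {token}
    for _ in range(max_deletions):
        nxt = set()
        for t in frontier:
            for i in range(len(t)):
                nxt.add(t[:i] + t[i + 1:])
        nxt -= out
        out |= nxt
        frontier = nxt
    return out
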