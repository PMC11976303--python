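"""Canonicalization of raw name strings.

Every downstream component (parser, index, matcher, finder, retrieval)
operates on one standardized writing of each name.  Normalization does
four things, in order:

1. Unicode compatibility composition (NFKC), so fullwidth and other
   compatibility variants of ASCII characters collapse to ASCII.
2. A configurable special-character map (typographic quotes and dashes to
   their straight ASCII forms, exotic spaces to plain space); the
   multiplication sign ``×`` is the canonical hybrid sign and passes
   through unchanged.  A token-initial ``_x`` — the hybrid marker some
   backbones embed in name strings — is rewritten to ``×``.
3. Space repair: insert a space after each character configured to retain
   one (``.`` and ``)`` by default), collapse runs of whitespace to a
   single space, trim the ends.
4. Remove the space before each character configured to reject one
   (``)`` and ``,`` by default) and the space after each character
   configured to reject a following one (``(`` by default).

Letter case is deliberately preserved: case handling belongs to the
matcher, and spelling repair to the fuzzy cascade.  The transform is
idempotent.
"""

from __future__ import annotations

import re
import unicodedata

from .config import (
    DEFAULT_RETAIN_SPACE_AFTER,
    DEFAULT_STRIP_SPACE_AFTER,
    DEFAULT_STRIP_SPACE_BEFORE,
    ToolkitConfig,
    load_charmap,
)

_WS_RUN = re.compile(r"\s+")
# "_x" (or "_X") at a token boundary, directly before a letter or a space
# then a letter: GBIF-style hybrid marker.
_HYBRID_MARKER = re.compile(r"(?:(?<=\s)|^)_[xX]\s*(?=[^\W\d_])")

_default_charmap: dict[int, str] | None = None


def _charmap() -> dict[int, str]:
    global _default_charmap
    if _default_charmap is None:
        _default_charmap = load_charmap(ToolkitConfig().charmap_path)
    return _default_charmap


def normalize_name(
    raw: str,
    *,
    charmap: dict[int, str] | None = None,
    retain_space_after: str = DEFAULT_RETAIN_SPACE_AFTER,
    strip_space_before: str = DEFAULT_STRIP_SPACE_BEFORE,
    strip_space_after: str = DEFAULT_STRIP_SPACE_AFTER,
) -> str:
    """Return the canonical writing of ``raw``.

    Total and idempotent; the empty string maps to itself.

    >>> normalize_name("Acer   palmatum")
    'Acer palmatum'
    >>> normalize_name("Quercus robur ( L. )")
    'Quercus robur (L.)'
    """
    if not raw:
        return ""
    s = unicodedata.normalize("NFKC", raw)
    s = s.translate(charmap if charmap is not None else _charmap())
    for ch in retain_space_after:
        s = s.replace(ch, ch + " ")
    s = _WS_RUN.sub(" ", s).strip()
    for ch in strip_space_before:
        s = s.replace(" " + ch, ch)
    for ch in strip_space_after:
        s = s.replace(ch + " ", ch)
    # after space repair, so the marker is recognized at token boundaries
    s = _HYBRID_MARKER.sub("×", s)
    return s


def normalize_with_config(raw: str, config: ToolkitConfig) -> str:
    """``normalize_name`` driven by a :class:`ToolkitConfig`."""
    return normalize_name(
        raw,
        charmap=config.charmap,
        retain_space_after=config.retain_space_after,
        strip_space_before=config.strip_space_before,
        strip_space_after=config.strip_space_after,
    )
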