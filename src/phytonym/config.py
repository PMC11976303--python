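"""Toolkit configuration.

One :class:`ToolkitConfig` object carries every tunable the services
share — batch limits, page-size bounds, the fuzzy-matching mode, the
special-character mapping and the dataset registry — so no route or CLI
command hard-codes its own numbers.  Configs load from a simple
``key = value`` text file; the character map and dataset registry are
plain two-column TSV files shipped as package data and overridable per
config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

_DATA_DIR = Path(__file__).parent / "data"

#: Characters after which a space is enforced during normalization.
DEFAULT_RETAIN_SPACE_AFTER = ".)"
#: Characters whose preceding space is removed during normalization.
DEFAULT_STRIP_SPACE_BEFORE = "),"
#: Characters whose following space is removed during normalization.
DEFAULT_STRIP_SPACE_AFTER = "("


def load_charmap(path: str | Path) -> dict[int, str]:
    """Read a two-column (codepoint, replacement) TSV into a ``str.translate`` map.

    Replacement escapes: ``\\s`` is a space, ``\\0`` deletes the character.
    Lines starting with ``#`` and blank lines are ignored.
    """
    mapping: dict[int, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        src, _, repl = line.partition("\t")
        repl = repl.rstrip("\n")
        if repl == "\\s":
            repl = " "
        elif repl == "\\0":
            repl = ""
        cp = int(src.strip().removeprefix("U+"), 16)
        mapping[cp] = repl
    return mapping


def load_dataset_registry(path: str | Path) -> dict[str, str]:
    """Read the datasetID → display-name registry (order-preserving)."""
    registry: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        code, _, name = line.partition("\t")
        registry[code.strip()] = name.strip()
    return registry


@dataclass
class ToolkitConfig:
    """Shared tunables; defaults mirror the hosted service's documented limits."""

    #: Maximum names accepted in one matching submission.
    batch_limit: int = 1000
    default_page_size: int = 20
    max_page_size: int = 200
    #: "per_token": each aligned token may differ by up to d edits.
    #: "whole_string": the concatenated name may differ by up to d edits.
    fuzzy_mode: str = "per_token"
    retain_space_after: str = DEFAULT_RETAIN_SPACE_AFTER
    strip_space_before: str = DEFAULT_STRIP_SPACE_BEFORE
    strip_space_after: str = DEFAULT_STRIP_SPACE_AFTER
    charmap_path: Path = field(default=_DATA_DIR / "charmap.tsv")
    datasets_path: Path = field(default=_DATA_DIR / "datasets.tsv")
    #: Minimum token count for a free-text find to be emitted (1 keeps
    #: genus-only hits).
    finder_min_tokens: int = 1

    def __post_init__(self) -> None:
        if self.fuzzy_mode not in ("per_token", "whole_string"):
            raise ValueError(f"unknown fuzzy_mode: {self.fuzzy_mode!r}")
        self._charmap: dict[int, str] | None = None
        self._registry: dict[str, str] | None = None

    @property
    def charmap(self) -> dict[int, str]:
        if self._charmap is None:
            self._charmap = load_charmap(self.charmap_path)
        return self._charmap

    @property
    def dataset_registry(self) -> dict[str, str]:
        if self._registry is None:
            self._registry = load_dataset_registry(self.datasets_path)
        return self._registry

    def dataset_priority(self, dataset_id: str) -> int:
        """Tie-break rank of a dataset (registry order; unknown datasets last)."""
        try:
            return list(self.dataset_registry).index(dataset_id)
        except ValueError:
            return len(self.dataset_registry)


_INT_KEYS = {"batch_limit", "default_page_size", "max_page_size", "finder_min_tokens"}
_PATH_KEYS = {"charmap_path", "datasets_path"}
_STR_KEYS = {"fuzzy_mode", "retain_space_after", "strip_space_before", "strip_space_after"}


def load_config(path: str | Path) -> ToolkitConfig:
    """Load a ``key = value`` config file; unknown keys raise ``ValueError``."""
    kwargs: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = key.strip(), value.strip()
        if key in _INT_KEYS:
            kwargs[key] = int(value)
        elif key in _PATH_KEYS:
            kwargs[key] = Path(value)
        elif key in _STR_KEYS:
            kwargs[key] = value
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return ToolkitConfig(**kwargs)  # type: ignore[arg-type]


DEFAULT_CONFIG = ToolkitConfig()
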