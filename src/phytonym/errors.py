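"""Exception types shared across the toolkit."""


class PhytonymError(Exception):
    """Base class for toolkit errors."""


class SchemaError(PhytonymError, ValueError):
    """An input table lacks a required column or has an unusable layout."""


class BatchLimitError(PhytonymError, ValueError):
    """A batch submission exceeds the configured name limit."""

    def __init__(self, n_names: int, limit: int):
        self.n_names = n_names
        self.limit = limit
        super().__init__(
            f"batch of {n_names} names exceeds the {limit}-name submission limit"
        )


class RecordNotFoundError(PhytonymError, LookupError):
    """A record ID does not exist in the store."""
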