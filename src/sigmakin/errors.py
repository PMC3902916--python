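"""Exceptions shared across the pipeline."""


class SigmakinError(Exception):
    """Base class for pipeline errors."""


class DegenerateArrayError(SigmakinError):
    """Raised when an array cannot be centered (MAD = 0 or < 2 finite values)."""


class ConstantProfileError(SigmakinError):
    """Raised when a correlation is requested for a constant profile."""


class UnresolvableIdentifiersError(SigmakinError):
    """Raised when requested gene/regulator identifiers are absent from the data."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"identifiers not found: {', '.join(self.missing)}")
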