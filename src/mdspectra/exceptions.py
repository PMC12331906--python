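"""Exception hierarchy shared across the package."""


class MDSpectraError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MDSpectraError, ValueError):
    """A caller-supplied argument violates a precondition."""


class InvalidDataError(MDSpectraError, ValueError):
    """Input data is structurally present but inconsistent (NaNs, duplicates, ...)."""


class ShieldingParseError(MDSpectraError, ValueError):
    """A shielding text block could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class UndefinedSimilarityError(MDSpectraError, ValueError):
    """Cosine similarity requested against an all-zero vector."""


class SchemaError(MDSpectraError, ValueError):
    """A columnar file does not match the expected dataset schema."""
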