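"""Exception hierarchy shared across the package.

CLI exit-code mapping: :class:`ValidationError` -> 2,
:class:`DataIntegrityError` -> 3, anything else -> 1.
"""


class OffpopError(Exception):
    """Base class for all package errors."""


class ValidationError(OffpopError):
    """Malformed input, unsupported value, or bad configuration."""

    exit_code = 2


class ParameterError(ValidationError):
    """A function parameter is outside its documented domain."""


class UnsupportedLengthError(ValidationError):
    """Candidate sequence length outside the supported 21-25 nt range."""


class DataIntegrityError(OffpopError):
    """Inputs contradict each other (e.g. VCF REF vs stored sequence)."""

    exit_code = 3


class PenaltyLookupError(OffpopError):
    """A required penalty-table entry is missing; names the missing key."""

    def __init__(self, key: str):
        self.key = key
        super().__init__(f"no penalty entry for {key!r}")


class GenerationError(OffpopError):
    """Synthetic-data spec cannot be realized as requested."""
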