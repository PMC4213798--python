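"""Exception types shared across the package."""


class MlclustError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MlclustError, ValueError):
    """Raised when an operation receives input violating its contract."""


class FastaParseError(MlclustError, ValueError):
    """Raised on malformed FASTA input; message carries the line number."""
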