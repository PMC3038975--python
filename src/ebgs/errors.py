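"""Exception hierarchy.

Validation and format errors map to CLI exit code 2, numerical failures
to exit code 3.
"""


class EbgsError(Exception):
    """Base class for all package errors."""


class ValidationError(EbgsError, ValueError):
    """Input violates a documented contract (bad IDs, codes, shapes)."""


class FormatError(EbgsError, ValueError):
    """A file could not be parsed (ragged rows, unmappable symbols, ...)."""


class NumericalError(EbgsError, RuntimeError):
    """A linear-algebra step failed (singular or non-PSD covariance)."""
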