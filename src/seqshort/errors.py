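"""Exception hierarchy shared across the package.

Exit codes for the command line follow the convention: 0 success,
2 validation/format error, 3 configuration error.
"""


class SeqShortError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(SeqShortError):
    """An input violates a documented invariant (bad values, empty bags...)."""

    exit_code = 2


class ShapeError(ValidationError):
    """An array has the wrong shape; the message names the offending axis."""


class FormatError(ValidationError):
    """A container on disk is missing datasets/attributes or is corrupt."""


class ConfigurationError(SeqShortError):
    """A configuration value is inconsistent or refers to something absent."""

    exit_code = 3
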