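"""Exception hierarchy shared across the package.

CLI exit codes: validation-type errors map to 1, :class:`UnassignableError`
maps to 2.
"""


class HmwgsError(Exception):
    """Base class for all package errors."""


class FormatError(HmwgsError):
    """Malformed input file (missing column, bad value, duplicate row)."""


class ValidationError(HmwgsError):
    """A domain invariant is violated."""


class InsufficientDataError(HmwgsError):
    """Too few observations for the requested statistic."""


class ConfigurationError(HmwgsError):
    """Inconsistent configuration, e.g. a subunit missing from a lookup table."""


class UnassignableError(HmwgsError):
    """No consistent peak-to-locus assignment exists."""

    def __init__(self, message: str, peaks=None):
        super().__init__(message)
        self.peaks = list(peaks) if peaks is not None else []
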