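"""Exception hierarchy.

All package errors derive from :class:`NapscopeError` so callers (and the
CLI) can distinguish expected domain failures from genuine bugs.
"""


class NapscopeError(Exception):
    """Base class for all napscope errors."""


class TopologyError(NapscopeError):
    """Unknown landmark/angle identifier or an invalid triplet table."""


class DomainError(NapscopeError, ValueError):
    """An input value outside its documented domain (e.g. coordinate > 1)."""


class DegenerateGeometryError(NapscopeError):
    """A limb vector collapsed to zero length; the joint angle is undefined."""


class EmptySeriesError(NapscopeError):
    """An operation that needs at least one present sample got none."""


class DesignError(NapscopeError):
    """A study table is not a complete subjects x conditions x angles crossing."""


class DegenerateDataError(NapscopeError):
    """Data carry no usable signal for a test (all-zero differences, constant ranks)."""


class FormatError(NapscopeError):
    """A file does not match the documented schema (wrong header, bad layout)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConfigError(NapscopeError):
    """An invalid simulator or run configuration; names the offending field."""


class InputError(NapscopeError):
    """An unreadable or empty input source."""
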