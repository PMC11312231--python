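"""Typed exceptions raised across the package."""


class PeriolocError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PeriolocError, ValueError):
    """A parameter violates its contract (e.g. even median kernel)."""


class InvalidInputError(PeriolocError, ValueError):
    """An input array or file violates its contract."""


class EmptyMaskError(InvalidInputError):
    """An operation requiring foreground pixels received an empty mask."""


class ShapeMismatchError(InvalidInputError):
    """Two arrays that must share dimensions do not."""


class SchemaError(InvalidInputError):
    """A file on disk violates the expected schema; names the offending field."""
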