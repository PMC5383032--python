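"""Exception types shared across the package."""


class CvdsynthError(Exception):
    """Base class for all package errors."""


class ParseError(CvdsynthError):
    """A cell could not be parsed (names the offending row)."""


class SchemaError(CvdsynthError):
    """A file or frame does not match the expected schema or category labels."""


class ValidationError(CvdsynthError):
    """A domain invariant is violated (names the offending record)."""


class FeasibilityError(CvdsynthError):
    """A constrained resolution problem has no solution."""
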