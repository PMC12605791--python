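"""Exception hierarchy shared across the package."""


class HsDetectError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HsDetectError):
    """A file could not be parsed (malformed line, bad value)."""


class SchemaError(HsDetectError):
    """Content is parseable but violates the expected schema
    (missing subfields, mismatched feature schemas, absent labels)."""


class ValidationError(HsDetectError):
    """Values are structurally fine but semantically invalid
    (non-positive volumes, incompatible affines, empty features)."""


class DegenerateDataError(HsDetectError):
    """Data with no usable variance (zero TBV variance, constant
    intensities) that makes a regression or z-score undefined."""
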