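"""Exception hierarchy shared across butlrkit."""


class ButlrKitError(Exception):
    """Base class for all butlrkit errors."""


class InvalidParameterError(ButlrKitError, ValueError):
    """A parameter violates its precondition (e.g. non-positive resolution)."""


class QueryParseError(ButlrKitError, ValueError):
    """A region string could not be parsed into a genomic interval."""


class NotFoundError(ButlrKitError, KeyError):
    """A feature id, chromosome, or matrix key is absent from its table."""


class FormatError(ButlrKitError):
    """A file does not conform to the expected on-disk format."""


class CorruptFileError(FormatError):
    """A file is structurally recognised but truncated or inconsistent."""


class EncodingError(ButlrKitError):
    """Input matrices cannot be encoded (e.g. conflicting symmetric values)."""


class DegenerateInputError(ButlrKitError):
    """Input is structurally valid but degenerate (e.g. all bins masked)."""
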