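"""Package exception hierarchy."""


class PhylostageError(Exception):
    """Base class for all errors raised by phylostage."""


class ValidationError(PhylostageError, ValueError):
    """Invalid in-memory data: bad values, inconsistent identifiers, empty input."""


class ParseError(ValidationError):
    """A file could not be parsed into a valid object; message names the offending row."""
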