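"""Exception hierarchy.

Parsing and validation failures always carry enough context (column name,
CSV row number) to locate the offending input; nothing is silently coerced.
"""


class GaitError(Exception):
    """Base class for all gaitkit errors."""


class FormatError(GaitError):
    """A file does not match the expected dialect (e.g. missing column)."""


class ValidationError(GaitError):
    """A value violates a domain invariant (bad paw label, negative time...)."""


class InsufficientDataError(GaitError):
    """Too few observations to compute the requested quantity."""


class UnsupportedMeasurementError(GaitError):
    """A required optional input (e.g. the contact-area time series) is absent."""


class ConfigurationError(GaitError):
    """Parameter combination is physically or statistically inadmissible."""


class UndefinedCorrelationError(GaitError):
    """Correlation requested on a zero-variance vector."""
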