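"""Exception hierarchy for the recurrence-plot pipeline."""


class RpcrossError(Exception):
    """Base class for all package errors."""


class SpacingError(RpcrossError):
    """Time column is not equally spaced within tolerance."""


class MissingColumnError(RpcrossError, KeyError):
    """Named data column absent from the input file."""


class ParseError(RpcrossError):
    """A cell could not be parsed as a number (row index reported)."""


class InsufficientDataError(RpcrossError):
    """Series too short for the requested operation."""


class DegenerateSeriesError(RpcrossError):
    """Series (or weight vector) has zero variance."""


class EmbeddingLengthError(RpcrossError):
    """Series too short for the requested (dim, tau) embedding."""


class ConfigurationError(RpcrossError):
    """Invalid parameter value or unknown option label."""


class UndefinedEntropyError(RpcrossError):
    """Entropy requested for an empty run-length histogram."""


class InsufficientScanError(RpcrossError):
    """Too few valid scan points for breakpoint selection."""
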