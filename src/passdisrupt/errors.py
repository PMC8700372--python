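"""Exception hierarchy for the passdisrupt pipeline.

Every stage raises a subclass of :class:`PassDisruptError`, so callers can
catch one type at the pipeline boundary while tests can assert on the
specific failure mode.
"""


class PassDisruptError(Exception):
    """Base class for all package errors."""


class TrackingFormatError(PassDisruptError):
    """A tracking or event file violates the expected schema."""


class OrderingError(PassDisruptError):
    """Timestamps or events are not in the required temporal order."""


class ConfigurationError(PassDisruptError):
    """An operation was configured with invalid parameters."""


class LookupError_(PassDisruptError):
    """An entity (team, player) is unknown to the metadata."""


class DataGapError(PassDisruptError):
    """A required player or frame is missing from the tracking data."""


class DegenerateInputError(PassDisruptError):
    """Input is too degenerate for the operation (e.g. identical positions)."""


class InsufficientDataError(PassDisruptError):
    """Not enough observations to run a statistical procedure."""


class ConsistencyError(PassDisruptError):
    """Event data is internally inconsistent (e.g. reception before pass)."""
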