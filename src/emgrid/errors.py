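"""Exception hierarchy.

Every error raised by the package derives from :class:`EmgridError`. The
pipeline attaches the name of the failing stage to the exception's
``stage`` attribute so batch runs can report where a recording failed.
"""


class EmgridError(Exception):
    """Base class for all emgrid errors."""

    stage: str | None = None


class GridSpecError(EmgridError, ValueError):
    """Invalid grid specification (blocks outside grid, overlaps, ...)."""


class UnknownChannelError(EmgridError, KeyError):
    """Channel identifier not present in the layout."""


class InvalidSpecError(EmgridError, ValueError):
    """Invalid synthetic source / force specification."""


class InvalidConfigError(EmgridError, ValueError):
    """Invalid processing configuration (band vs. Nyquist, ...)."""


class MissingDataError(EmgridError):
    """A required input (e.g. force channel) is absent."""


class InsufficientDataError(EmgridError):
    """Recording or window too short for the requested operation."""


class UnrecoverableChannelError(EmgridError):
    """Bad channel with no valid neighbor to interpolate from."""


class EmptySegmentationError(EmgridError):
    """Segmentation produced no clusters."""


class EmptySelectionError(EmgridError):
    """Empty channel set where at least one channel is required."""


class InvalidMetadataError(EmgridError, ValueError):
    """Non-physical or missing anatomical metadata."""


class IntegrityError(EmgridError):
    """Duplicate or incomplete rows while assembling a results table."""


class DesignError(EmgridError):
    """Factorial design deficient for the requested ANOVA."""
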