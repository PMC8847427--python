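"""Exception hierarchy for masknano.

All validation-type failures derive from :class:`MaskNanoError` so callers
(and the CLI) can distinguish bad input (exit code 1) from I/O trouble
(exit code 2).
"""


class MaskNanoError(Exception):
    """Base class for all masknano-specific errors."""


class SchemaError(MaskNanoError):
    """A table is missing a mandatory column or has an unusable layout."""


class ValidationError(MaskNanoError):
    """A value violates a domain invariant (negative size, duplicate id, ...)."""


class ConfigurationError(MaskNanoError):
    """A dosimetry or pipeline configuration is incomplete or inconsistent."""


class DetectionError(MaskNanoError):
    """An expected image feature (e.g. the fiber cross-section) was not found."""


class PlacementError(MaskNanoError):
    """Synthetic particle placement failed after bounded retries."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved
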