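"""Exception hierarchy for the gaitmoment package.

All errors derive from :class:`GaitMomentError` so callers can catch the
package's failures with a single except clause; the leaf classes mirror the
distinct failure modes of the pipeline (schema, alignment, dimensions, ...).
"""


class GaitMomentError(Exception):
    """Base class for all gaitmoment errors."""


class SchemaError(GaitMomentError):
    """A required column or field is missing from an input table."""


class EmptyDataError(GaitMomentError):
    """No usable rows/windows remain after validation."""


class ParameterError(GaitMomentError, ValueError):
    """An operation parameter is out of its valid domain."""


class AlignmentError(GaitMomentError):
    """Predictor and target recordings cannot be brought to a common grid."""


class DimensionError(GaitMomentError):
    """Array shapes are inconsistent with the declared model dimensions."""


class DegenerateChannelError(GaitMomentError):
    """A channel has zero variance and cannot be z-scored."""


class InsufficientDataError(GaitMomentError):
    """The trace is shorter than one analysis window."""


class ConfigurationError(GaitMomentError):
    """A run or model configuration is internally inconsistent."""


class DivergenceError(GaitMomentError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class DomainError(GaitMomentError, ValueError):
    """A scalar input (mass, height, ...) is outside its physical domain."""
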