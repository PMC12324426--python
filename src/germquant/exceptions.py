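"""Exception hierarchy for germquant.

Every error raised by the measurement layer derives from :class:`GermquantError`
so pipeline drivers can distinguish domain failures (bad data, degenerate
regions) from programming errors.
"""


class GermquantError(Exception):
    """Base class for all germquant domain errors."""


class ParameterError(GermquantError, ValueError):
    """An input parameter violates its contract; the message names the field."""


class FormatError(GermquantError):
    """A file exists but its layout does not match what was requested."""


class ConsistencyError(GermquantError):
    """Two inputs that must agree (shapes, category sets, groups) do not."""


class ZeroVarianceError(GermquantError):
    """A statistic that requires spread was asked of a constant region."""


class SegmentationError(GermquantError):
    """Mask generation or cropping produced an empty/invalid region."""


class InsufficientDataError(GermquantError):
    """Too few samples/pixels/profile points for the requested statistic."""


class EmptySelectionError(GermquantError):
    """A pixel gate selected nothing; carries the selection counts."""

    def __init__(self, message: str, n_posterior: int = 0, n_above_threshold: int = 0):
        super().__init__(message)
        self.n_posterior = n_posterior
        self.n_above_threshold = n_above_threshold
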