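"""Exception hierarchy shared by all pipeline stages."""


class AdiagaitError(Exception):
    """Base class for all package errors."""


class ParameterError(AdiagaitError, ValueError):
    """A configuration or call parameter violates its contract."""


class FormatError(AdiagaitError, ValueError):
    """An input file or container does not match the expected schema."""


class GapError(AdiagaitError, ValueError):
    """Missing samples (NaN) in a signal that must be gap-free."""


class SegmentationError(AdiagaitError, ValueError):
    """Gait-cycle segmentation failed (too few maxima, degenerate signal)."""


class InsufficientDataError(AdiagaitError, ValueError):
    """Not enough samples/cycles for the requested statistic."""


class DegenerateDataError(AdiagaitError, ValueError):
    """Data degenerate for the requested statistic (zero variance, all-zero diffs)."""
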