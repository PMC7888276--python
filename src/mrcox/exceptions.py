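"""Exception hierarchy for mrcox.

All errors raised by the package derive from :class:`MRCoxError`, so callers
can catch a single base class at pipeline level.
"""


class MRCoxError(Exception):
    """Base class for all mrcox errors."""


class InfeasibleCalibrationError(MRCoxError):
    """The requested exposure variance explained cannot be realized."""


class HarmonizationError(MRCoxError):
    """Duplicate instrument records have irreconcilable alleles."""


class EmptyInstrumentError(MRCoxError):
    """No overlapping variants between genotypes and instrument weights."""


class DegenerateRegressionError(MRCoxError):
    """A regression required for rescaling has zero predictor variance."""


class NoEventsError(MRCoxError):
    """A survival model was requested on data with no events."""


class NoEstimatesError(MRCoxError):
    """Meta-analysis received no usable study-level estimates."""


class UndefinedRatioError(MRCoxError):
    """Wald ratio requested with a zero SNP-exposure effect."""


class InsufficientInstrumentsError(MRCoxError):
    """An estimator needs more instruments than were supplied."""


class InsufficientStrataError(MRCoxError):
    """Fewer than two usable environment strata for the G x E analysis."""


class UnidentifiedError(MRCoxError):
    """No heterogeneity in instrument strength across strata; the
    gene-environment slope is not identified."""
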