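"""Exception hierarchy for ebfit.

All ebfit errors derive from :class:`EbfitError` so callers can catch the
whole family; each subclass also derives from the closest built-in
(``ValueError`` for bad inputs) so generic handling keeps working.
"""


class EbfitError(Exception):
    """Base class for all ebfit errors."""


class InvalidArgumentError(EbfitError, ValueError):
    """A scalar argument violates its precondition (negative power, etc.)."""


class InvalidTestError(EbfitError, ValueError):
    """A test record violates the protocol invariants (e.g. ΔHR ≤ 0)."""


class IncompleteSeriesError(EbfitError, ValueError):
    """An HR series is missing one of the required protocol time points."""


class NotApplicableError(EbfitError, ValueError):
    """The method cannot be applied to this record (e.g. HR outside the
    nomogram's 120–170 bpm window); mirrors the exclusion rules used when
    the comparator methods were validated."""


class ConfigurationError(EbfitError, ValueError):
    """A required configuration object (e.g. nomogram table) is missing
    or malformed."""


class InsufficientDataError(EbfitError, ValueError):
    """Too few paired observations to compute the requested statistic."""


class DegenerateRegressionError(EbfitError, ValueError):
    """Regression input has no usable variation (constant predictor,
    perfectly collinear design)."""


class FormatError(EbfitError, ValueError):
    """An input file is missing required columns or is otherwise unreadable."""


class SpecError(EbfitError, ValueError):
    """A cohort specification is internally inconsistent or infeasible."""
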