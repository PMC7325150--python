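"""Exception hierarchy for rankenrich."""


class RankEnrichError(Exception):
    """Base class for all rankenrich errors."""


class UnrecognisedFormatError(RankEnrichError, ValueError):
    """No known differential-expression table dialect matches the columns seen."""


class AmbiguousFormatError(UnrecognisedFormatError):
    """More than one dialect matches equally well and no hint was given."""


class ValidationError(RankEnrichError, ValueError):
    """Input data violates a precondition (non-finite score, bad p-value, ...)."""


class DegenerateTestError(RankEnrichError, ValueError):
    """The enrichment test is not well posed (singular covariance, empty complement)."""


class PlotLimitError(RankEnrichError, ValueError):
    """Too many contrasts for the plotting routines."""
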