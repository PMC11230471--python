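"""Exception hierarchy for the striatophot pipeline.

Every error raised on purpose by the package derives from
:class:`StriatophotError`, so callers can catch pipeline failures without
swallowing programming errors.
"""


class StriatophotError(Exception):
    """Base class for all striatophot errors."""


class SchemaError(StriatophotError):
    """An input table is missing required columns or has the wrong layout."""


class SamplingError(StriatophotError):
    """A time base is not uniformly sampled within tolerance."""


class DataError(StriatophotError):
    """Trace values violate basic data requirements (NaN, inf, length)."""


class ParameterError(StriatophotError):
    """A configuration or function parameter is outside its valid range."""


class FitError(StriatophotError):
    """A regression could not be fit (e.g. degenerate predictor)."""


class NumericGuardError(StriatophotError):
    """A divisor fell below the numeric guard epsilon."""
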