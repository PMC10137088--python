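"""Exception hierarchy shared by every pipeline stage."""


class SpectroScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpectroScreenError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(SpectroScreenError):
    """Input data violates a contract (labels, counts, ranges of records)."""


class RangeError(SpectroScreenError):
    """A requested wavenumber interval falls outside the data axis."""


class DegenerateInputError(SpectroScreenError):
    """An operation is undefined on this input (zero norm, zero area, ...)."""


class ParameterError(SpectroScreenError):
    """A numeric parameter is out of its admissible domain."""


class SizeError(SpectroScreenError):
    """Too few data points for the operation."""


class UndefinedMetricError(SpectroScreenError):
    """A performance metric has a zero denominator."""


class EstimatorError(SpectroScreenError):
    """An attribution estimator was configured below its feasibility limit."""


class ConfigError(SpectroScreenError):
    """A run/simulation configuration is internally inconsistent."""
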