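"""Exception hierarchy shared across the package."""


class GrousevisError(ValueError):
    """Base class for all domain errors raised by this package."""


class ParameterError(GrousevisError):
    """A scalar argument is outside its documented validity range."""


class OutOfRangeError(GrousevisError):
    """A requested wavelength/level is outside the data coverage."""


class DegenerateInputError(GrousevisError):
    """Input data are structurally unusable (flat, empty, all-zero...)."""


class FitFailureError(GrousevisError):
    """The optimisation objective has no usable interior minimum."""


class CoverageError(GrousevisError):
    """A spectrum does not cover the wavelength range an operation needs."""
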