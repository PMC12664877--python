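"""Exception hierarchy shared across the package."""


class DartdoseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DartdoseError, ValueError):
    """A precondition on user-supplied values was violated."""


class ConfigurationError(DartdoseError):
    """An object or parameter set is internally inconsistent."""


class UndefinedRatioError(DartdoseError):
    """A count-ratio estimator has a zero reference denominator."""


class CalibrationError(DartdoseError):
    """A range-model calibration target is unattainable or non-identifiable."""


class SolverError(DartdoseError):
    """A linear solve failed to converge; carries residual diagnostics."""


class NoCrossingError(DartdoseError):
    """An isodose level is outside the range of a radial profile."""


class ExtrapolationError(DartdoseError):
    """An interpolation target lies outside the tabulated sweep."""
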