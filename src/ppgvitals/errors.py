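"""Exception hierarchy for the vital-signs pipeline.

Every error raised by this package derives from :class:`PpgVitalsError`,
so callers can catch one base class at pipeline boundaries while tests
can assert on the specific failure mode.
"""


class PpgVitalsError(Exception):
    """Base class for all package errors."""


class ValidationError(PpgVitalsError, ValueError):
    """Malformed input: bad parameter value, inconsistent series, bad payload."""


class DomainError(ValidationError):
    """A value outside the mathematical domain of an operation
    (e.g. an SpO2 above the calibration polynomial's maximum)."""


class ConvergenceError(PpgVitalsError):
    """An iterative adjustment (LED emission control) failed to reach its
    target band within the allowed number of iterations."""


class InsufficientBeatsError(PpgVitalsError):
    """Too few detected beats to compute the requested quantity."""


class DegenerateSignalError(PpgVitalsError):
    """A signal feature needed as a denominator vanished (e.g. zero DC)."""


class NoEstimateError(PpgVitalsError):
    """No dominant spectral peak exists in the plausible band; the window
    carries no usable respiratory modulation."""


class WindowRejectedError(PpgVitalsError):
    """All vital-sign estimators failed on a window; it yields no record."""
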