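"""Exception hierarchy.

Every error raised by the library derives from :class:`HemospecError`, so
callers (and the CLI) can distinguish computation failures from usage bugs.
"""


class HemospecError(Exception):
    """Base class for all hemospec errors."""


class MalformedInputError(HemospecError):
    """An input file or table violates the documented format."""


class ValidationError(HemospecError):
    """A value is out of its physically admissible range."""


class ExtrapolationError(HemospecError):
    """A requested wavelength grid falls outside the basis support."""


class AlignmentError(HemospecError):
    """Spectrum and basis are not on the same wavelength grid."""


class DegenerateFitError(HemospecError):
    """The unmixing design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = tuple(columns) if columns else ()


class UndefinedFractionError(HemospecError):
    """Derivative fractions are undefined because total heme is zero."""


class UndefinedHemolysisError(HemospecError):
    """Hemolysis is undefined because the suspension has zero total heme."""


class DegenerateSeriesError(HemospecError):
    """A kinetic series is flat; the transition model is unidentifiable."""


class NonConvergenceError(HemospecError):
    """The kinetic fit did not converge within the allowed restarts."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class UnreachableThresholdError(HemospecError):
    """A threshold lies outside the fitted transition range."""


class UndefinedRateError(HemospecError):
    """A formation rate is undefined for a non-positive transition time."""


class NoMinimumError(HemospecError):
    """The ROS-rate parabola has no minimum (non-convex case)."""


class DomainError(HemospecError):
    """An argument is outside the model's domain (e.g. negative oxygen)."""


class ConfigError(HemospecError):
    """A synthetic-data configuration is internally inconsistent."""
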