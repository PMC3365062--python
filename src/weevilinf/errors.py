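"""Exception hierarchy for the weevilinf pipeline."""


class WeevilinfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(WeevilinfError, ValueError):
    """Input data violate a documented invariant (bad ranges, missing values...)."""


class ConfigurationError(WeevilinfError, ValueError):
    """A run/truth configuration is internally inconsistent."""


class CalibrationError(WeevilinfError, RuntimeError):
    """The requested variance-explained band cannot be reached; carries the
    achievable range when known."""

    def __init__(self, message, achievable=None):
        super().__init__(message)
        self.achievable = achievable


class SingularDesignError(WeevilinfError, ValueError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class InsufficientDataError(WeevilinfError, ValueError):
    """Fewer observations than parameters."""


class DegenerateFitError(WeevilinfError, ValueError):
    """Residual sum of squares is zero; the Gaussian AIC is undefined."""


class NoCandidateError(WeevilinfError, RuntimeError):
    """No admissible candidate variable remains (all rank deficient)."""
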