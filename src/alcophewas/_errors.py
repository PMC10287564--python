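"""Exception hierarchy shared across the package."""


class AlcophewasError(Exception):
    """Base class for package errors."""


class ConfigurationError(AlcophewasError):
    """Invalid configuration value (frequencies, hazards, windows...)."""


class ValidationError(AlcophewasError):
    """Invalid data passed to an operation (negative volumes, bad p-values...)."""


class DataIntegrityError(AlcophewasError):
    """Input data violate a structural contract (events outside follow-up...)."""


class EstimationError(AlcophewasError):
    """An estimator cannot be computed from the data provided."""


class ConvergenceError(EstimationError):
    """Iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
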