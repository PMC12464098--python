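"""Exception types shared across the package."""


class FloranatError(Exception):
    """Base class for package errors."""


class ConfigurationError(FloranatError):
    """A configuration file or column mapping does not resolve."""


class ValidationError(FloranatError):
    """Input data violates a domain invariant (bad flag, duplicate id, ...)."""


class ConvergenceError(FloranatError):
    """A model fit failed to converge."""


class SeparationError(ConvergenceError):
    """Perfect separation in a logistic fit; the MLE does not exist."""

    def __init__(self, message: str, predictor: str | None = None):
        super().__init__(message)
        self.predictor = predictor
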