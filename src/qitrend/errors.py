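"""Exception types shared across the package."""


class QitrendError(Exception):
    """Base class for package-specific errors."""


class SchemaError(QitrendError):
    """An input table does not have the expected columns/types."""


class ValidationError(QitrendError):
    """Input values violate a documented invariant."""


class ModelInfeasibleError(QitrendError):
    """A model cannot be fitted on the given data (e.g. no events)."""


class ConvergenceError(QitrendError):
    """An iterative fit did not converge within the allowed iterations."""
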