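"""Exception hierarchy shared across the package."""


class AmdtoxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AmdtoxError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(AmdtoxError):
    """Input table violates the expected schema (missing columns, ids, charges)."""


class ValidationError(AmdtoxError):
    """Input values are structurally valid but inconsistent (e.g. conflicting labels)."""


class ConvergenceError(AmdtoxError):
    """Iterative solver failed to reach the requested tolerance."""

    def __init__(self, message: str, worst_residual: float | None = None):
        super().__init__(message)
        self.worst_residual = worst_residual
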