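"""Exception hierarchy shared across the package."""


class DropmixError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DropmixError, ValueError):
    """An input violates a documented precondition."""


class PlacementError(ValidationError):
    """Requested droplet contact sites cannot be placed without overlap."""


class NumericalError(DropmixError, RuntimeError):
    """A numerical routine failed to converge; carries diagnostics."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FitError(NumericalError):
    """A curve fit did not converge or is degenerate."""
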