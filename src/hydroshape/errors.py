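"""Exception types shared across the package."""


class HydroshapeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HydroshapeError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(HydroshapeError, ValueError):
    """Too few data points to perform a fit or statistic."""


class DegenerateDataError(HydroshapeError, ValueError):
    """Data has no variance along the direction a fit requires."""


class FrameValidationError(HydroshapeError, ValueError):
    """A molecular frame violates a structural invariant."""


class ConnectivityError(HydroshapeError, ValueError):
    """Umbrella windows do not overlap; the histogram chain is broken."""


class ConvergenceError(HydroshapeError, RuntimeError):
    """An iterative solver did not reach tolerance within max_iter."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class PackingError(HydroshapeError, RuntimeError):
    """Rejection packing failed; the requested density is not achievable."""


class ConfigurationError(HydroshapeError, ValueError):
    """A generator or run configuration is internally inconsistent."""


class StepSizeError(HydroshapeError, RuntimeError):
    """A Metropolis chain accepted no moves during burn-in."""
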