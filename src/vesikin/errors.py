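"""Exception hierarchy for the package.

``DataError`` covers malformed or inconsistent input (exit code 1 in the
CLI); ``FitError`` covers optimisation failures (exit code 2).
"""


class VesikinError(Exception):
    """Base class for all package-specific errors."""


class DataError(VesikinError, ValueError):
    """Invalid, inconsistent or malformed input data."""


class FitError(VesikinError, RuntimeError):
    """A least-squares fit failed to converge or is ill-posed."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateTraceError(FitError):
    """Trace carries no resolvable exponential signal (flat amplitude)."""


class SimulationError(VesikinError, RuntimeError):
    """The ODE integrator reported a failure."""
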