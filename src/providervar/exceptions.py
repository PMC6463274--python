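"""Exception hierarchy.

``ValidationError`` covers malformed inputs and contract violations detected
before any numerics run; ``NumericalError`` covers failures of the numerical
routines themselves (non-convergence, unidentifiable signal).  The CLI maps
them to distinct exit codes.
"""


class ProviderVarError(Exception):
    """Base class for all package errors."""


class ValidationError(ProviderVarError, ValueError):
    """Invalid input data or configuration."""


class NumericalError(ProviderVarError, RuntimeError):
    """A numerical routine failed to produce a usable result."""


class InfeasibleMomentsError(NumericalError):
    """The estimated moment targets violate a universal moment inequality,
    so no distribution — and hence no adjusted data set — can match them."""


class ConvergenceError(NumericalError):
    """An iterative fit did not converge; carries the best iterate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
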