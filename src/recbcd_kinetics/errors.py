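"""Exception hierarchy shared by all analysis stages.

Exit-code mapping used by the CLI: configuration problems -> 2,
data problems -> 3, numerical/fitting failures -> 4.
"""


class RecbcdKineticsError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RecbcdKineticsError, ValueError):
    """An argument violates a documented precondition."""


class DataError(RecbcdKineticsError, ValueError):
    """Input records are malformed or insufficient for the analysis."""


class FitError(RecbcdKineticsError, RuntimeError):
    """A nonlinear fit failed to converge or the data cannot constrain it.

    ``best_so_far`` carries the best parameter set reached before failure,
    when one exists.
    """

    def __init__(self, message, best_so_far=None):
        super().__init__(message)
        self.best_so_far = best_so_far


class NumericalError(RecbcdKineticsError, RuntimeError):
    """An ODE integration or linear-algebra step failed; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
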