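"""Exception hierarchy for the tegma pipeline.

Every stage raises a subclass of :class:`TegmaError`, so callers (and the
CLI) can distinguish bad configuration from bad data from numerical failure.
"""

from __future__ import annotations


class TegmaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TegmaError, ValueError):
    """A generator or run configuration violates its invariants."""


class ParseError(TegmaError, ValueError):
    """A CSV fixture could not be parsed; names the offending row/column."""

    def __init__(self, message: str, *, column: str | None = None,
                 row: int | None = None):
        super().__init__(message)
        self.column = column
        self.row = row


class DegenerateDataError(TegmaError, ValueError):
    """Data admit no estimate (zero variance, identical x, too few points).

    ``variable`` names the degenerate input when known.
    """

    def __init__(self, message: str, *, variable: str | None = None):
        super().__init__(message)
        self.variable = variable


class FitFailure(TegmaError, RuntimeError):
    """Nonlinear fit did not converge within the iteration cap.

    Carries the best parameter vector reached so the bootstrap can account
    for failures without losing information.
    """

    def __init__(self, message: str, *, best_params=None, sse: float | None = None):
        super().__init__(message)
        self.best_params = best_params
        self.sse = sse


class NoSolutionError(TegmaError, ValueError):
    """Model inversion has no solution at the requested target.

    Distinct from :class:`FitFailure`: the fit succeeded but the target lies
    beyond the asymptote (or on the wrong side of the curve).
    """


class BootstrapUnstableError(TegmaError, RuntimeError):
    """Fewer than the required fraction of bootstrap replicates succeeded.

    Carries the partial cutoff distribution for diagnosis.
    """

    def __init__(self, message: str, *, cutoffs=None, n_requested: int = 0,
                 n_succeeded: int = 0):
        super().__init__(message)
        self.cutoffs = cutoffs
        self.n_requested = n_requested
        self.n_succeeded = n_succeeded
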