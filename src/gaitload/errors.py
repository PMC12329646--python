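"""Exception hierarchy for the gaitload pipeline.

All errors derive from :class:`GaitLoadError` so callers can catch the whole
family; configuration and range errors additionally derive from ``ValueError``
for idiomatic use.
"""

from __future__ import annotations


class GaitLoadError(Exception):
    """Base class for all gaitload errors."""


class ConfigurationError(GaitLoadError, ValueError):
    """Invalid or inconsistent configuration values."""


class OutOfRangeError(GaitLoadError, ValueError):
    """An input fell outside its documented domain."""


class InvalidModelError(GaitLoadError, ValueError):
    """A musculoskeletal model violates a structural invariant."""


class InvalidInputError(GaitLoadError, ValueError):
    """Inputs to an operation are mutually inconsistent (e.g. grid mismatch)."""


class InsufficientStrengthError(GaitLoadError):
    """The recruitment problem is infeasible: a required net moment cannot be
    produced with non-negative muscle forces at the given strengths.

    Attributes
    ----------
    row : int | None
        Index of the moment-balance row with the largest violation.
    sample : int | None
        Phase-sample index, when raised from a trace solve.
    """

    def __init__(self, message: str, row: int | None = None,
                 sample: int | None = None):
        super().__init__(message)
        self.row = row
        self.sample = sample


class ConvergenceError(GaitLoadError):
    """An iterative solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class InsufficientDataError(GaitLoadError, ValueError):
    """Too few observations for the requested statistic."""


class NumericalError(GaitLoadError):
    """Non-finite values or instability detected during integration."""
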