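"""Exception hierarchy.

Data-shape problems (bad CSV, broken invariants) are ``DataError`` subclasses;
model-fitting problems are ``FitError`` subclasses.  The CLI maps these to
distinct exit codes.
"""


class PalpkitError(Exception):
    """Base class for all package errors."""


class DataError(PalpkitError):
    """Invalid or malformed input data."""


class MalformedInputError(DataError):
    """Rows out of order, duplicate timestamps, non-finite values."""


class FormatError(DataError):
    """Missing/renamed columns or fields in an input file."""


class DegenerateTrialError(DataError):
    """Trial too short to analyze (fewer than 2 frames)."""


class DomainError(DataError, ValueError):
    """Argument outside its documented domain."""


class UndefinedMetricError(PalpkitError):
    """Metric has no defined value for this trial (e.g. no movement frames)."""


class UndefinedDirectionError(UndefinedMetricError):
    """Fingertip coincides with the target; direction toward it is undefined."""


class FitError(PalpkitError):
    """Model estimation failed."""


class ConvergenceError(FitError):
    """Optimizer failed to converge; no silent fallback is attempted."""


class SeparationError(FitError):
    """Complete/quasi-complete separation in the logistic model."""

    def __init__(self, factor: str):
        self.factor = factor
        super().__init__(
            f"complete separation: outcome is constant within a level of {factor!r}"
        )


class DegenerateFitError(FitError):
    """Response is constant (or otherwise uninformative); model is unidentifiable."""
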