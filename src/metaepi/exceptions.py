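"""Exception hierarchy for dataset validation and model fitting."""


class MetaEpiError(Exception):
    """Base class for all package errors."""


class SchemaError(MetaEpiError):
    """An input table violates the CSV schema (missing column, bad value)."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column '{column}'")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.row = row
        self.column = column


class ReferentialIntegrityError(MetaEpiError):
    """A trial references a meta-analysis id absent from the MA table."""


class InvalidTrialError(MetaEpiError):
    """A trial's 2x2 table is unusable (non-positive denominator)."""


class DegenerateDesignError(MetaEpiError):
    """The meta-regression design matrix is rank deficient for an MA."""


class CovariateDegenerateError(MetaEpiError):
    """An adjustment covariate is constant across trials, so the adjusted
    model is not identifiable; callers fall back to the unadjusted fit."""


class NoEligibleMAsError(MetaEpiError):
    """Eligibility filtering removed every meta-analysis."""


class ConvergenceWarning(UserWarning):
    """REML iteration stopped at max_iter without meeting the tolerance."""
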