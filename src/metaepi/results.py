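"""Result containers for the two-step analysis.

All effects are carried on the natural-log scale internally; odds-ratio /
ratio-of-odds-ratios scales appear only in confidence-interval fields and
reporting helpers, to avoid double rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class EffectEstimate:
    """A single trial's log odds ratio and its Woolf standard error.

    ``exp(log_or) < 1`` means benefit of the experimental intervention after
    direction re-coding.  A double-zero trial (no event, or no non-event, in
    both arms) carries no estimate and is flagged instead.
    """

    trial_id: str
    log_or: float | None
    se: float | None
    corrected: bool = False
    excluded_double_zero: bool = False

    @property
    def odds_ratio(self) -> float | None:
        return None if self.log_or is None else math.exp(self.log_or)


@dataclass
class MAResult:
    """Step-1 output: one meta-analysis' log ratio of odds ratios.

    ``log_ror`` is the coefficient of the primary-care indicator in the
    random-effects meta-regression; ``exp(log_ror)`` is the ROR (primary care
    vs secondary/tertiary care).  ``tau2_within`` is the residual
    between-trial variance within the MA.
    """

    ma_id: str
    log_ror: float
    se_log_ror: float
    tau2_within: float
    k_pc: int
    k_st: int
    method: str = "REML"
    adjusted_for: str | None = None
    converged: bool = True

    @property
    def ror(self) -> float:
        return math.exp(self.log_ror)


@dataclass
class PooledResult:
    """Step-2 output: the combined log-ROR across meta-analyses.

    ``ci_low``/``ci_high`` are the 95% confidence limits on the ROR scale
    (exponentiated).  ``Q`` is Cochran's heterogeneity statistic computed with
    fixed-effect weights, ``i2`` the derived percentage with its 95% CI, and
    ``tau2_between`` the between-meta-analysis variance.  With a single input
    the heterogeneity fields are None (not applicable).
    """

    log_ror_combined: float
    se: float
    ci_low: float
    ci_high: float
    Q: float | None
    df: int
    i2: float | None
    i2_ci_low: float | None
    i2_ci_high: float | None
    tau2_between: float | None
    k: int
    method: str = "REML"
    ci_method: str = "wald"

    @property
    def ror(self) -> float:
        return math.exp(self.log_ror_combined)


@dataclass
class SubgroupResult:
    """Subgroup pooling plus the between-group interaction test.

    The interaction statistic is the fixed-effect Q between the
    random-effects subgroup estimates, referred to a chi-square distribution
    with (number of groups - 1) degrees of freedom.
    """

    grouping: str
    per_group: dict[str, PooledResult]
    q_interaction: float
    df_interaction: int
    p_interaction: float
    excluded: dict[str, int] = field(default_factory=dict)


@dataclass
class FilterReport:
    """Bookkeeping for one eligibility/de-duplication stage."""

    stage: str
    n_mas_in: int
    n_mas_out: int
    n_trials_in: int
    n_trials_out: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_mas_out > self.n_mas_in or self.n_trials_out > self.n_trials_in:
            raise ValueError(f"stage '{self.stage}': output counts exceed input counts")
        for _, rule in self.exclusions:
            if not rule:
                raise ValueError(f"stage '{self.stage}': exclusion without a rule name")
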