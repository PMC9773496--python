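"""The two-step ratio-of-odds-ratios analysis.

Step 1 (:func:`estimate_ma_ror`): within each meta-analysis, regress trial
log odds ratios on a primary-care indicator by random-effects
meta-regression; the indicator's coefficient is the log ratio of odds
ratios (ROR = OR in primary-care trials / OR in secondary- or
tertiary-care trials).  ROR < 1 means smaller apparent benefit in primary
care.  Sensitivity variants adjust for one dichotomised risk-of-bias
domain at a time.

Step 2 (:func:`pool_rors`): the per-MA log-RORs, weighted by the inverse of
their sampling variances plus a between-MA variance, are combined by
random-effects meta-analysis; heterogeneity is summarised by Cochran's Q,
I^2 with its 95% CI, and the between-MA tau^2.  Subgroup analyses pool
within groups of MAs and compare them with a fixed-effect interaction Q
test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import RandomEffectsMetaAnalysis, RandomEffectsMetaRegression
from .exceptions import CovariateDegenerateError, DegenerateDesignError
from .io import ROB_DOMAINS
from .results import MAResult, PooledResult, SubgroupResult

HIGH_OR_UNCLEAR = {"high", "unclear", "missing"}


def _prepare(effects: pd.DataFrame) -> pd.DataFrame:
    usable = effects[~effects["excluded_double_zero"].astype(bool)].copy()
    usable = usable[np.isfinite(usable["log_or"]) & np.isfinite(usable["se"])]
    return usable


def _check_step1_preconditions(usable: pd.DataFrame, ma_id: str) -> tuple[int, int]:
    k_pc = int((usable["setting"] == "PC").sum())
    k_st = int((usable["setting"] == "ST").sum())
    if len(usable) < 3:
        raise ValueError(f"MA '{ma_id}': fewer than 3 analysable trials ({len(usable)})")
    if k_pc == 0 or k_st == 0:
        raise ValueError(f"MA '{ma_id}': both settings must be represented (PC={k_pc}, ST={k_st})")
    return k_pc, k_st


def estimate_ma_ror(
    effects: pd.DataFrame,
    method: str = "reml",
    ci_method: str = "wald",
    ma_id: str | None = None,
) -> MAResult:
    """Step 1: one meta-analysis' log-ROR by random-effects meta-regression.

    ``effects`` needs columns ``log_or``, ``se``, ``setting`` (and optionally
    ``excluded_double_zero``, which removes flagged rows).  Requires at least
    3 analysable trials with both settings represented.
    """
    if "excluded_double_zero" not in effects.columns:
        effects = effects.assign(excluded_double_zero=False)
    usable = _prepare(effects)
    if ma_id is None:
        ma_id = str(usable["ma_id"].iloc[0]) if "ma_id" in usable.columns and len(usable) else "?"
    k_pc, k_st = _check_step1_preconditions(usable, ma_id)
    x = (usable["setting"] == "PC").to_numpy(dtype=float)[:, None]
    y = usable["log_or"].to_numpy(dtype=float)
    v = usable["se"].to_numpy(dtype=float) ** 2
    try:
        reg = RandomEffectsMetaRegression(method=method, ci_method=ci_method).fit(x, y, v)
    except DegenerateDesignError as err:
        raise DegenerateDesignError(f"MA '{ma_id}': {err}") from err
    return MAResult(
        ma_id=ma_id,
        log_ror=float(reg.coef_[0]),
        se_log_ror=float(reg.bse_[1]),
        tau2_within=float(reg.tau2_),
        k_pc=k_pc,
        k_st=k_st,
        method=method.upper(),
        adjusted_for=None,
        converged=bool(reg.converged_),
    )


def dichotomise_rob(levels: pd.Series) -> np.ndarray:
    """Risk-of-bias covariate: 1 = high, unclear or missing; 0 = low."""
    return levels.isin(HIGH_OR_UNCLEAR).to_numpy(dtype=float)


def estimate_ma_ror_adjusted(
    effects: pd.DataFrame,
    rob_domain: str,
    method: str = "reml",
    ci_method: str = "wald",
    ma_id: str | None = None,
) -> MAResult:
    """Step 1, adjusted: log-ROR controlling for one risk-of-bias domain.

    The domain judgement is dichotomised (high/unclear/missing vs low) and
    entered as a second moderator.  A constant covariate raises
    :class:`CovariateDegenerateError` (the caller should fall back to the
    unadjusted estimate); a covariate collinear with the setting indicator
    raises :class:`DegenerateDesignError`.
    """
    if rob_domain not in ROB_DOMAINS:
        raise ValueError(f"unknown risk-of-bias domain '{rob_domain}'")
    col = f"rob_{rob_domain}"
    if col not in effects.columns:
        raise ValueError(f"effects table lacks column '{col}'")
    if "excluded_double_zero" not in effects.columns:
        effects = effects.assign(excluded_double_zero=False)
    usable = _prepare(effects)
    if ma_id is None:
        ma_id = str(usable["ma_id"].iloc[0]) if "ma_id" in usable.columns and len(usable) else "?"
    k_pc, k_st = _check_step1_preconditions(usable, ma_id)
    x = (usable["setting"] == "PC").to_numpy(dtype=float)
    z = dichotomise_rob(usable[col])
    if np.all(z == z[0]):
        raise CovariateDegenerateError(
            f"MA '{ma_id}': risk-of-bias covariate '{rob_domain}' is constant"
        )
    y = usable["log_or"].to_numpy(dtype=float)
    v = usable["se"].to_numpy(dtype=float) ** 2
    try:
        reg = RandomEffectsMetaRegression(method=method, ci_method=ci_method).fit(
            np.column_stack([x, z]), y, v
        )
    except DegenerateDesignError as err:
        raise DegenerateDesignError(f"MA '{ma_id}': {err}") from err
    return MAResult(
        ma_id=ma_id,
        log_ror=float(reg.coef_[0]),
        se_log_ror=float(reg.bse_[1]),
        tau2_within=float(reg.tau2_),
        k_pc=k_pc,
        k_st=k_st,
        method=method.upper(),
        adjusted_for=rob_domain,
        converged=bool(reg.converged_),
    )


def pool_rors(
    results: list[MAResult],
    method: str = "reml",
    ci_method: str = "wald",
) -> PooledResult:
    """Step 2: combined ROR across meta-analyses by random-effects pooling.

    Non-converged step-1 results are excluded.  With a single MA the pooled
    result equals its input and heterogeneity is marked not applicable.
    """
    usable = [r for r in results if r.converged]
    if not usable:
        raise ValueError("no converged meta-analysis results to pool")
    y = np.array([r.log_ror for r in usable])
    v = np.array([r.se_log_ror**2 for r in usable])
    ma = RandomEffectsMetaAnalysis(method=method, ci_method=ci_method).fit(y, v)
    return PooledResult(
        log_ror_combined=ma.effect_,
        se=ma.se_,
        ci_low=float(np.exp(ma.ci_low_)),
        ci_high=float(np.exp(ma.ci_high_)),
        Q=ma.q_,
        df=ma.df_,
        i2=ma.i2_,
        i2_ci_low=ma.i2_ci_[0],
        i2_ci_high=ma.i2_ci_[1],
        tau2_between=ma.tau2_,
        k=ma.k_,
        method=method.upper(),
        ci_method=ci_method,
    )


def interaction_test(estimates: list[float], ses: list[float]) -> tuple[float, int, float]:
    """Fixed-effect Q test for differences between subgroup estimates.

    Q = sum_g w_g (theta_g - theta_bar)^2 with w_g = 1/se_g^2 and theta_bar
    the weighted mean; p from chi-square with (groups - 1) df.
    """
    theta = np.asarray(estimates, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    if theta.shape[0] < 2:
        raise ValueError("interaction test needs at least two groups")
    theta_bar = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_bar) ** 2))
    df = theta.shape[0] - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def subgroup_analysis(
    results: list[MAResult],
    labels: dict[str, str],
    grouping: str = "subgroup",
    method: str = "reml",
    ci_method: str = "wald",
) -> SubgroupResult:
    """Pool within labelled groups of MAs and test for interaction.

    ``labels`` maps ma_id to a group level; MAs with a None label are
    excluded (counted in ``excluded``).  Each group is pooled with its own
    between-MA tau^2; single-MA groups keep their estimate (heterogeneity
    not applicable) and still enter the interaction test.
    """
    usable = [r for r in results if r.converged]
    groups: dict[str, list[MAResult]] = {}
    excluded: dict[str, int] = {}
    for r in usable:
        label = labels.get(r.ma_id)
        if label is None:
            excluded["unlabelled"] = excluded.get("unlabelled", 0) + 1
            continue
        groups.setdefault(str(label), []).append(r)
    if len(groups) < 2:
        raise ValueError(f"subgroup analysis '{grouping}' needs at least two non-empty groups")
    per_group = {
        level: pool_rors(rs, method=method, ci_method=ci_method)
        for level, rs in sorted(groups.items())
    }
    q, df, p = interaction_test(
        [pg.log_ror_combined for pg in per_group.values()],
        [pg.se for pg in per_group.values()],
    )
    return SubgroupResult(
        grouping=grouping,
        per_group=per_group,
        q_interaction=q,
        df_interaction=df,
        p_interaction=p,
        excluded=excluded,
    )
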