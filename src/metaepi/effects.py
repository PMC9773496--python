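"""Trial-level odds ratios on the log scale.

Each 2x2 table (events/no-events by experimental/control arm) yields a log
odds ratio with the Woolf large-sample standard error
``sqrt(1/a + 1/b + 1/c + 1/d)``.  Outcome events are re-coded per
meta-analysis so that OR < 1 always means benefit of the experimental
intervention.  Sparse tables where exactly one arm has zero events (or zero
non-events) receive the Haldane-Anscombe 0.5 continuity correction to every
cell; tables with no event in both arms, or no non-event in both arms, carry
no information about the OR and are excluded from estimation.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InvalidTrialError
from .io import Dataset
from .results import EffectEstimate

EFFECT_COLUMNS = [
    "trial_id",
    "ma_id",
    "setting",
    "log_or",
    "se",
    "corrected",
    "excluded_double_zero",
]


def recode_direction(trial: Mapping, direction: str) -> dict:
    """Re-code a trial's events so that OR < 1 indicates benefit.

    For an MA whose outcome event is beneficial (e.g. smoking cessation),
    events and non-events are swapped in both arms, making the re-coded OR
    the reciprocal of the raw OR.  Harmful-event MAs pass through unchanged.
    The swap is an involution: applying it twice restores the original trial.
    """
    trial = dict(trial)
    if direction == "event_harmful":
        return trial
    if direction != "event_beneficial":
        raise ValueError(f"unknown benefit direction '{direction}'")
    trial["events_exp"] = trial["n_exp"] - trial["events_exp"]
    trial["events_ctrl"] = trial["n_ctrl"] - trial["events_ctrl"]
    return trial


def compute_log_or(trial: Mapping, continuity_correction: bool = True) -> EffectEstimate:
    """Log odds ratio and standard error for one (already re-coded) trial.

    With cells a = events_exp, b = n_exp - events_exp, c = events_ctrl,
    d = n_ctrl - events_ctrl:

        log OR = ln(ad / bc),   se = sqrt(1/a + 1/b + 1/c + 1/d)

    If exactly one of the four cells patterns is empty, 0.5 is added to all
    four cells first (``corrected=True``).  If both arms have zero events, or
    both have zero non-events, the OR is inestimable and the trial is
    flagged ``excluded_double_zero``.
    """
    n_exp, n_ctrl = int(trial["n_exp"]), int(trial["n_ctrl"])
    if n_exp <= 0 or n_ctrl <= 0:
        raise InvalidTrialError(
            f"trial '{trial.get('trial_id', '?')}': non-positive arm size"
        )
    a = float(trial["events_exp"])
    c = float(trial["events_ctrl"])
    b = n_exp - a
    d = n_ctrl - c
    trial_id = str(trial.get("trial_id", ""))
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        return EffectEstimate(trial_id, None, None, corrected=False, excluded_double_zero=True)
    corrected = False
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            return EffectEstimate(trial_id, None, None, corrected=False, excluded_double_zero=True)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(trial_id, log_or, se, corrected=corrected, excluded_double_zero=False)


def compute_effects(dataset: Dataset, continuity_correction: bool = True) -> pd.DataFrame:
    """Effect table for every trial in a dataset.

    Applies each owning MA's direction re-coding, then the log-OR
    computation.  Returns one row per trial with columns
    ``trial_id, ma_id, setting, log_or, se, corrected, excluded_double_zero``;
    double-zero trials keep their row with NaN effect fields so downstream
    stages can count them.
    """
    directions = dataset.mas.set_index("ma_id")["benefit_direction"].to_dict()
    rows = []
    for _, t in dataset.trials.iterrows():
        recoded = recode_direction(t, directions[t["ma_id"]])
        est = compute_log_or(recoded, continuity_correction=continuity_correction)
        rows.append(
            {
                "trial_id": t["trial_id"],
                "ma_id": t["ma_id"],
                "setting": t["setting"],
                "log_or": np.nan if est.log_or is None else est.log_or,
                "se": np.nan if est.se is None else est.se,
                "corrected": est.corrected,
                "excluded_double_zero": est.excluded_double_zero,
            }
        )
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)
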