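"""Eligibility and de-duplication rules for meta-epidemiological cohorts.

The selection rules, applied in a fixed order:

1. :func:`select_ma_per_review` — at most one meta-analysis per systematic
   review: the primary-efficacy-outcome MA when flagged, otherwise the MA
   with the most trials.
2. :func:`dedup_within_ma` — a trial listed twice inside one MA keeps only
   the row with the largest randomised sample size.
3. :func:`dedup_across_mas` — a trial appearing in several selected MAs is
   kept only in the MA from the most recent systematic review.
4. :func:`filter_eligible_mas` — retained MAs need at least 3 trials and at
   least one primary-care and one secondary/tertiary-care trial (three
   being the minimum for a meta-regression).

Ties the rules do not determine (equal sample sizes, equal review years)
are broken deterministically — first-listed row, lexicographically smallest
review_id — and recorded in the report so runs are reproducible.
"""

from __future__ import annotations

import logging

import pandas as pd

from .exceptions import NoEligibleMAsError
from .io import Dataset
from .results import FilterReport

logger = logging.getLogger(__name__)


def _report(stage, din: Dataset, dout: Dataset, exclusions) -> FilterReport:
    return FilterReport(
        stage=stage,
        n_mas_in=din.n_mas,
        n_mas_out=dout.n_mas,
        n_trials_in=din.n_trials,
        n_trials_out=dout.n_trials,
        exclusions=exclusions,
    )


def select_ma_per_review(dataset: Dataset) -> tuple[Dataset, FilterReport]:
    """Keep at most one MA per review: primary outcome first, then most trials."""
    mas = dataset.mas
    trial_counts = dataset.trials.groupby("ma_id").size()
    keep: list[str] = []
    exclusions: list[tuple[str, str]] = []
    for _, group in mas.groupby("review_id", sort=False):
        primaries = group[group["is_primary_outcome"]]
        if len(primaries):
            chosen = primaries["ma_id"].iloc[0]
            rule = "not the primary-outcome MA of its review"
        else:
            counts = group["ma_id"].map(lambda m: trial_counts.get(m, 0))
            chosen = group["ma_id"].iloc[int(counts.to_numpy().argmax())]
            rule = "fewer trials than the selected MA of its review"
        keep.append(chosen)
        for ma_id in group["ma_id"]:
            if ma_id != chosen:
                exclusions.append((ma_id, rule))
    kept = set(keep)
    out = Dataset(
        dataset.trials[dataset.trials["ma_id"].isin(kept)].reset_index(drop=True),
        mas[mas["ma_id"].isin(kept)].reset_index(drop=True),
        dataset.provenance,
    )
    for ma_id, rule in exclusions:
        logger.info("select_ma_per_review: excluded MA %s (%s)", ma_id, rule)
    return out, _report("select_ma_per_review", dataset, out, exclusions)


def dedup_within_ma(dataset: Dataset) -> tuple[Dataset, FilterReport]:
    """One row per (ma_id, trial_id): keep the largest sample_size duplicate."""
    trials = dataset.trials
    exclusions: list[tuple[str, str]] = []
    keep_idx: list[int] = []
    for (ma_id, trial_id), group in trials.groupby(["ma_id", "trial_id"], sort=False):
        if len(group) == 1:
            keep_idx.append(group.index[0])
            continue
        # stable idxmax: the first-listed row among equal maxima is kept
        winner = group.index[int(group["sample_size"].to_numpy().argmax())]
        if (group["sample_size"] == group["sample_size"].max()).sum() > 1:
            logger.info(
                "dedup_within_ma: tie on sample_size for trial %s in MA %s; keeping first listed",
                trial_id,
                ma_id,
            )
        keep_idx.append(winner)
        for idx in group.index:
            if idx != winner:
                exclusions.append((f"{ma_id}/{trial_id}", "duplicate within MA, smaller sample size"))
    out = Dataset(
        trials.loc[sorted(keep_idx)].reset_index(drop=True),
        dataset.mas.copy(),
        dataset.provenance,
    )
    return out, _report("dedup_within_ma", dataset, out, exclusions)


def dedup_across_mas(dataset: Dataset) -> tuple[Dataset, FilterReport]:
    """A trial in several MAs stays only in the most recent review's MA."""
    trials = dataset.trials
    review = dataset.mas.set_index("ma_id")[["review_id", "review_year"]]
    exclusions: list[tuple[str, str]] = []
    keep_idx: list[int] = []
    for trial_id, group in trials.groupby("trial_id", sort=False):
        if group["ma_id"].nunique() == 1:
            keep_idx.extend(group.index)
            continue
        meta = review.loc[group["ma_id"]]
        order = pd.DataFrame(
            {
                "idx": group.index,
                "year": meta["review_year"].to_numpy(),
                "review_id": meta["review_id"].to_numpy(),
                "ma_id": group["ma_id"].to_numpy(),
            }
        )
        best_year = order["year"].max()
        candidates = order[order["year"] == best_year]
        if candidates["review_id"].nunique() > 1:
            logger.info(
                "dedup_across_mas: tie on review_year for trial %s; keeping lexicographically "
                "smallest review_id",
                trial_id,
            )
        winner_review = candidates["review_id"].min()
        winners = candidates[candidates["review_id"] == winner_review]
        keep_idx.extend(winners["idx"].tolist())
        for _, row in order.iterrows():
            if row["idx"] not in set(winners["idx"]):
                exclusions.append(
                    (f"{row['ma_id']}/{trial_id}", "duplicate across MAs, older review")
                )
    out = Dataset(
        trials.loc[sorted(keep_idx)].reset_index(drop=True),
        dataset.mas.copy(),
        dataset.provenance,
    )
    return out, _report("dedup_across_mas", dataset, out, exclusions)


def filter_eligible_mas(
    dataset: Dataset, require_analysable: bool = False
) -> tuple[Dataset, FilterReport]:
    """Keep MAs with >= 3 trials and both care settings represented.

    With ``require_analysable=True`` the three-trial minimum counts only
    trials whose 2x2 table can contribute an odds ratio (drops double-zero
    trials before counting); by default selection precedes analysis and all
    listed trials count.
    """
    trials = dataset.trials
    if require_analysable:
        both_zero = (trials["events_exp"] == 0) & (trials["events_ctrl"] == 0)
        all_events = (trials["events_exp"] == trials["n_exp"]) & (
            trials["events_ctrl"] == trials["n_ctrl"]
        )
        countable = trials[~(both_zero | all_events)]
    else:
        countable = trials
    exclusions: list[tuple[str, str]] = []
    keep: list[str] = []
    for ma_id in dataset.mas["ma_id"]:
        sub = countable[countable["ma_id"] == ma_id]
        n_pc = int((sub["setting"] == "PC").sum())
        n_st = int((sub["setting"] == "ST").sum())
        if len(sub) < 3:
            exclusions.append((ma_id, "fewer than 3 trials"))
        elif n_pc == 0:
            exclusions.append((ma_id, "no PC trial"))
        elif n_st == 0:
            exclusions.append((ma_id, "no ST trial"))
        else:
            keep.append(ma_id)
    kept = set(keep)
    out = Dataset(
        trials[trials["ma_id"].isin(kept)].reset_index(drop=True),
        dataset.mas[dataset.mas["ma_id"].isin(kept)].reset_index(drop=True),
        dataset.provenance,
    )
    if out.n_mas == 0:
        raise NoEligibleMAsError("no meta-analysis satisfies the eligibility rules")
    return out, _report("filter_eligible_mas", dataset, out, exclusions)


def apply_all_filters(
    dataset: Dataset, require_analysable: bool = False
) -> tuple[Dataset, list[FilterReport]]:
    """The full selection cascade in its fixed order, with per-stage reports."""
    reports = []
    for step in (select_ma_per_review, dedup_within_ma, dedup_across_mas):
        dataset, rep = step(dataset)
        reports.append(rep)
    dataset, rep = filter_eligible_mas(dataset, require_analysable=require_analysable)
    reports.append(rep)
    return dataset, reports
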