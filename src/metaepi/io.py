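"""Data model and CSV/JSON input-output.

Two input tables describe a meta-epidemiological dataset:

``trials.csv``
    one row per randomised trial: 2x2 outcome counts (events / patients
    analysed per arm), care setting (``PC`` primary care, ``ST``
    secondary/tertiary care), owning meta-analysis, Cochrane risk-of-bias
    judgements and metadata.

``mas.csv``
    one row per meta-analysis: owning review, intervention and control
    classification, outcome-objectivity class and the direction in which the
    outcome event is coded.

Dialect: UTF-8, comma-separated, mandatory header, empty string = missing.
Missing risk-of-bias cells are coded ``"missing"`` on load.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from .exceptions import ReferentialIntegrityError, SchemaError
from .results import FilterReport, MAResult, PooledResult, SubgroupResult

SETTINGS = ("PC", "ST")
ROB_LEVELS = ("low", "high", "unclear", "missing")
ROB_DOMAINS = (
    "sequence_generation",
    "allocation_concealment",
    "blinding_participants_personnel",
    "blinding_outcome_assessors",
    "incomplete_outcome_data",
    "selective_reporting",
)
ROB_COLUMNS = tuple(f"rob_{d}" for d in ROB_DOMAINS)
INTERVENTION_TYPES = ("pharmacological", "non_pharmacological")
CONTROL_TYPES = ("active", "placebo", "no_added_intervention", "sham", "other")
OUTCOME_CLASSES = (
    "all_cause_mortality",
    "objective",
    "objective_influenced",
    "subjective",
    "unclear",
)
BENEFIT_DIRECTIONS = ("event_harmful", "event_beneficial")

TRIAL_MANDATORY = (
    "ma_id",
    "trial_id",
    "setting",
    "events_exp",
    "n_exp",
    "events_ctrl",
    "n_ctrl",
    "sample_size",
)
TRIAL_OPTIONAL = ("year", "n_centers") + ROB_COLUMNS
MA_COLUMNS = (
    "ma_id",
    "review_id",
    "review_year",
    "medical_field",
    "intervention_type",
    "control_type",
    "outcome_class",
    "benefit_direction",
    "is_primary_outcome",
)


@dataclass
class Dataset:
    """A validated meta-epidemiological dataset.

    ``trials`` and ``mas`` are DataFrames following the two CSV schemas.
    Duplicate (ma_id, trial_id) rows are permitted at load time; the
    de-duplication filters establish uniqueness, mirroring the selection
    process in which duplicates are resolved by explicit rules.
    """

    trials: pd.DataFrame
    mas: pd.DataFrame
    provenance: str = ""

    def copy(self) -> "Dataset":
        return Dataset(self.trials.copy(), self.mas.copy(), self.provenance)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_mas(self) -> int:
        return len(self.mas)

    def trials_of(self, ma_id: str) -> pd.DataFrame:
        return self.trials[self.trials["ma_id"] == ma_id]


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], which: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{which}: missing mandatory column(s) {missing}")


def _to_count(df: pd.DataFrame, col: str, which: str, minimum: int) -> pd.Series:
    try:
        vals = pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError):
        bad = pd.to_numeric(df[col], errors="coerce")
        row = int(bad.index[bad.isna()][0])
        raise SchemaError(f"{which}: non-numeric value '{df[col].iloc[row]}'", row=row, column=col)
    if (vals != vals.round()).any():
        row = int(vals.index[vals != vals.round()][0])
        raise SchemaError(f"{which}: non-integer count", row=row, column=col)
    vals = vals.astype(int)
    if (vals < minimum).any():
        row = int(vals.index[vals < minimum][0])
        raise SchemaError(f"{which}: value {vals.iloc[row]} below minimum {minimum}", row=row, column=col)
    return vals


def _check_enum(df: pd.DataFrame, col: str, levels: tuple[str, ...], which: str) -> None:
    bad = ~df[col].isin(levels)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"{which}: '{df[col].iloc[row]}' is not one of {levels}", row=row, column=col
        )


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a trials table (see module docstring)."""
    trials = trials.copy()
    _require_columns(trials, TRIAL_MANDATORY, "trials")
    trials["ma_id"] = trials["ma_id"].astype(str)
    trials["trial_id"] = trials["trial_id"].astype(str)
    _check_enum(trials, "setting", SETTINGS, "trials")
    for col in ("events_exp", "events_ctrl"):
        trials[col] = _to_count(trials, col, "trials", minimum=0)
    for col in ("n_exp", "n_ctrl", "sample_size"):
        trials[col] = _to_count(trials, col, "trials", minimum=1)
    for ev, n in (("events_exp", "n_exp"), ("events_ctrl", "n_ctrl")):
        bad = trials[ev] > trials[n]
        if bad.any():
            row = int(trials.index[bad][0])
            raise SchemaError(
                f"trials: {ev}={trials[ev].iloc[row]} exceeds {n}={trials[n].iloc[row]}",
                row=row,
                column=ev,
            )
    for col in ("year", "n_centers"):
        if col in trials.columns:
            trials[col] = pd.to_numeric(trials[col].replace("", pd.NA), errors="coerce").astype("Int64")
        else:
            trials[col] = pd.array([pd.NA] * len(trials), dtype="Int64")
    for col in ROB_COLUMNS:
        if col in trials.columns:
            trials[col] = trials[col].replace("", "missing").fillna("missing").astype(str)
            _check_enum(trials, col, ROB_LEVELS, "trials")
        else:
            trials[col] = "missing"
    return trials


def validate_mas(mas: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a meta-analysis table."""
    mas = mas.copy()
    _require_columns(mas, MA_COLUMNS, "mas")
    for col in ("ma_id", "review_id", "medical_field"):
        mas[col] = mas[col].astype(str)
    if mas["ma_id"].duplicated().any():
        dup = mas["ma_id"][mas["ma_id"].duplicated()].iloc[0]
        raise SchemaError(f"mas: duplicate ma_id '{dup}'", column="ma_id")
    mas["review_year"] = _to_count(mas, "review_year", "mas", minimum=0)
    _check_enum(mas, "intervention_type", INTERVENTION_TYPES, "mas")
    _check_enum(mas, "control_type", CONTROL_TYPES, "mas")
    _check_enum(mas, "outcome_class", OUTCOME_CLASSES, "mas")
    _check_enum(mas, "benefit_direction", BENEFIT_DIRECTIONS, "mas")
    truthy = {"true": True, "1": True, "false": False, "0": False}
    parsed = mas["is_primary_outcome"].astype(str).str.strip().str.lower().map(truthy)
    if parsed.isna().any():
        row = int(mas.index[parsed.isna()][0])
        raise SchemaError("mas: is_primary_outcome must be boolean", row=row, column="is_primary_outcome")
    mas["is_primary_outcome"] = parsed.astype(bool)
    return mas


def make_dataset(trials: pd.DataFrame, mas: pd.DataFrame, provenance: str = "") -> Dataset:
    """Validate both tables and their cross references into a Dataset."""
    trials = validate_trials(trials)
    mas = validate_mas(mas)
    known = set(mas["ma_id"])
    dangling = trials.loc[~trials["ma_id"].isin(known), "ma_id"]
    if len(dangling):
        raise ReferentialIntegrityError(
            f"trials reference ma_id '{dangling.iloc[0]}' absent from the MA table"
        )
    return Dataset(trials.reset_index(drop=True), mas.reset_index(drop=True), provenance)


def load_dataset(trials_path: str | Path, mas_path: str | Path) -> Dataset:
    """Load and validate a dataset from its two CSV files."""
    trials = pd.read_csv(trials_path, dtype=str, keep_default_na=False)
    mas = pd.read_csv(mas_path, dtype=str, keep_default_na=False)
    return make_dataset(trials, mas, provenance=f"loaded from {trials_path}, {mas_path}")


def save_dataset(dataset: Dataset, trials_path: str | Path, mas_path: str | Path) -> None:
    dataset.trials.to_csv(trials_path, index=False)
    dataset.mas.to_csv(mas_path, index=False)


# ---------------------------------------------------------------------------
# Result serialisation.  Tables go to CSV; nested results to JSON with
# full float precision (repr round-trip), so re-loading reproduces values
# bit-identically for integers and to stored precision for reals.
# ---------------------------------------------------------------------------


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"__type__": type(obj).__name__}
        for f in dataclasses.fields(obj):
            d[f.name] = _to_jsonable(getattr(obj, f.name))
        return d
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_results(results: Any, path: str | Path) -> None:
    """Write pipeline output to a round-trippable machine-readable file.

    DataFrames and lists of MAResult become CSV; single result objects
    (PooledResult, SubgroupResult, FilterReport) become JSON.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
        return
    if isinstance(results, list) and all(isinstance(r, MAResult) for r in results):
        cols = [f.name for f in dataclasses.fields(MAResult)]
        df = pd.DataFrame([dataclasses.asdict(r) for r in results], columns=cols)
        df.to_csv(path, index=False)
        return
    if isinstance(results, list) and all(isinstance(r, FilterReport) for r in results):
        rows = []
        for rep in results:
            for entity, rule in rep.exclusions:
                rows.append({"stage": rep.stage, "entity_id": entity, "rule": rule})
        pd.DataFrame(rows, columns=["stage", "entity_id", "rule"]).to_csv(path, index=False)
        return
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_to_jsonable(results), fh, indent=2)


def read_ma_results(path: str | Path) -> list[MAResult]:
    df = pd.read_csv(path, keep_default_na=True, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        adj = row["adjusted_for"]
        out.append(
            MAResult(
                ma_id=str(row["ma_id"]),
                log_ror=float(row["log_ror"]),
                se_log_ror=float(row["se_log_ror"]),
                tau2_within=float(row["tau2_within"]),
                k_pc=int(row["k_pc"]),
                k_st=int(row["k_st"]),
                method=str(row["method"]),
                adjusted_for=None if pd.isna(adj) else str(adj),
                converged=bool(row["converged"]),
            )
        )
    return out


def _pooled_from_json(d: dict) -> PooledResult:
    kwargs = {k: v for k, v in d.items() if k != "__type__"}
    return PooledResult(**kwargs)


def read_pooled_result(path: str | Path) -> PooledResult:
    with open(path, encoding="utf-8") as fh:
        return _pooled_from_json(json.load(fh))


def read_subgroup_result(path: str | Path) -> SubgroupResult:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    per_group = {k: _pooled_from_json(v) for k, v in d["per_group"].items()}
    return SubgroupResult(
        grouping=d["grouping"],
        per_group=per_group,
        q_interaction=d["q_interaction"],
        df_interaction=d["df_interaction"],
        p_interaction=d["p_interaction"],
        excluded=d.get("excluded", {}),
    )
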