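"""End-to-end pipeline: load/simulate -> filter -> effects -> two-step ROR.

The report bundle written to the output directory:

``filter_report.csv``      every excluded entity with the rule that removed it
``effects.csv``            per-trial log odds ratios
``ma_results.csv``         step-1 per-MA log-RORs
``pooled.json``            step-2 combined ROR with heterogeneity
``subgroup_<name>.json``   subgroup pooling + interaction test
``adjusted_<domain>.csv``/``adjusted_<domain>_pooled.json``
                           risk-of-bias-adjusted step-1 and step-2 results
``summary.txt``            human-readable forest-style report
``run_log.txt``            versions, seed, every tie-break and fallback

Numbers in ``summary.txt`` are rendered from the machine-readable files;
the text report is never the source of any value.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effects import compute_effects
from .exceptions import CovariateDegenerateError, DegenerateDesignError
from .filters import apply_all_filters
from .io import ROB_DOMAINS, Dataset, load_dataset, save_dataset, write_results
from .results import FilterReport, MAResult, PooledResult, SubgroupResult
from .ror import estimate_ma_ror, estimate_ma_ror_adjusted, pool_rors, subgroup_analysis
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

SUBGROUPS = ("intervention_type", "control_group", "outcome_objectivity")

# control-group dichotomy: inactive = placebo, no added intervention to
# usual care, or sham; 'other' comparators are excluded from this subgroup
_CONTROL_DICHOTOMY = {
    "active": "active",
    "placebo": "inactive",
    "no_added_intervention": "inactive",
    "sham": "inactive",
    "other": None,
}
# outcome dichotomy: objective = all-cause mortality or objectively
# assessed; subjective = clinician/patient-influenced or subjective;
# 'unclear' excluded
_OUTCOME_DICHOTOMY = {
    "all_cause_mortality": "objective",
    "objective": "objective",
    "objective_influenced": "subjective",
    "subjective": "subjective",
    "unclear": None,
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (files xor simulation)."""

    trials_path: str | None = None
    mas_path: str | None = None
    simulate: SimulationConfig | None = None
    tau2_method: str = "reml"
    ci_method: str = "wald"
    subgroups: tuple[str, ...] = SUBGROUPS
    adjust_rob: tuple[str, ...] = ROB_DOMAINS
    continuity_correction: bool = True
    require_analysable: bool = False
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.trials_path is not None and self.mas_path is not None
        if from_files == (self.simulate is not None):
            raise ValueError("exactly one input source: (trials_path, mas_path) xor simulate")
        if self.tau2_method not in ("reml", "dl"):
            raise ValueError("tau2_method must be 'reml' or 'dl'")
        if self.ci_method not in ("wald", "kh"):
            raise ValueError("ci_method must be 'wald' or 'kh'")
        for s in self.subgroups:
            if s not in SUBGROUPS:
                raise ValueError(f"unknown subgroup '{s}'; choose from {SUBGROUPS}")
        for d in self.adjust_rob:
            if d not in ROB_DOMAINS:
                raise ValueError(f"unknown risk-of-bias domain '{d}'")


@dataclass
class ReportBundle:
    """In-memory pipeline output mirroring the files on disk."""

    dataset: Dataset
    filter_reports: list[FilterReport]
    effects: pd.DataFrame
    ma_results: list[MAResult]
    failed_mas: list[tuple[str, str]]
    pooled: PooledResult
    subgroups: dict[str, SubgroupResult]
    adjusted: dict[str, tuple[list[MAResult], PooledResult, list[str]]]


def subgroup_labels(dataset: Dataset, grouping: str) -> dict[str, str | None]:
    """ma_id -> subgroup level for one of the planned groupings."""
    mas = dataset.mas
    if grouping == "intervention_type":
        return dict(zip(mas["ma_id"], mas["intervention_type"]))
    if grouping == "control_group":
        return {m: _CONTROL_DICHOTOMY[c] for m, c in zip(mas["ma_id"], mas["control_type"])}
    if grouping == "outcome_objectivity":
        return {m: _OUTCOME_DICHOTOMY[c] for m, c in zip(mas["ma_id"], mas["outcome_class"])}
    raise ValueError(f"unknown subgroup '{grouping}'")


def _step1(effects: pd.DataFrame, config: PipelineConfig):
    ma_results: list[MAResult] = []
    failed: list[tuple[str, str]] = []
    for ma_id, sub in effects.groupby("ma_id", sort=False):
        try:
            ma_results.append(
                estimate_ma_ror(sub, method=config.tau2_method, ci_method=config.ci_method, ma_id=str(ma_id))
            )
        except (ValueError, DegenerateDesignError) as err:
            failed.append((str(ma_id), str(err)))
            logger.warning("step 1 failed for MA %s: %s", ma_id, err)
    return ma_results, failed


def _adjusted_step(effects: pd.DataFrame, trials: pd.DataFrame, domain: str, config: PipelineConfig):
    """Per-MA adjusted fits with fallback to the unadjusted estimate."""
    col = f"rob_{domain}"
    merged = effects.merge(
        trials[["ma_id", "trial_id", col]], on=["ma_id", "trial_id"], how="left"
    )
    results: list[MAResult] = []
    fallbacks: list[str] = []
    for ma_id, sub in merged.groupby("ma_id", sort=False):
        try:
            results.append(
                estimate_ma_ror_adjusted(
                    sub, domain, method=config.tau2_method, ci_method=config.ci_method, ma_id=str(ma_id)
                )
            )
        except (CovariateDegenerateError, DegenerateDesignError):
            try:
                res = estimate_ma_ror(
                    sub, method=config.tau2_method, ci_method=config.ci_method, ma_id=str(ma_id)
                )
                results.append(res)
                fallbacks.append(str(ma_id))
                logger.info(
                    "adjusted analysis (%s): MA %s fell back to the unadjusted estimate", domain, ma_id
                )
            except (ValueError, DegenerateDesignError):
                pass
        except ValueError:
            pass
    pooled = pool_rors(results, method=config.tau2_method, ci_method=config.ci_method)
    return results, pooled, fallbacks


def run_pipeline(config: PipelineConfig, write: bool = True) -> ReportBundle:
    """Execute the full two-step analysis and (optionally) write the bundle."""
    out_dir = Path(config.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "run_log.txt"
        handler = logging.FileHandler(log_path, mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root = logging.getLogger("metaepi")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    try:
        logger.info(
            "metaepi %s | python %s | numpy %s | pandas %s | seed %d",
            __version__, sys.version.split()[0], np.__version__, pd.__version__, config.seed,
        )
        if config.simulate is not None:
            sim_config = config.simulate.model_copy(update={"seed": config.seed})
            dataset, truth = simulate_dataset(sim_config)
            if write:
                save_dataset(dataset, out_dir / "trials.csv", out_dir / "mas.csv")
                truth.to_csv(out_dir / "ground_truth.csv")
        else:
            dataset = load_dataset(config.trials_path, config.mas_path)
        logger.info("input: %d MAs, %d trials", dataset.n_mas, dataset.n_trials)

        dataset, filter_reports = apply_all_filters(
            dataset, require_analysable=config.require_analysable
        )
        for rep in filter_reports:
            logger.info(
                "%s: MAs %d -> %d, trials %d -> %d",
                rep.stage, rep.n_mas_in, rep.n_mas_out, rep.n_trials_in, rep.n_trials_out,
            )

        effects = compute_effects(dataset, continuity_correction=config.continuity_correction)
        n_dz = int(effects["excluded_double_zero"].sum())
        if n_dz:
            logger.info("%d double-zero trial(s) excluded from estimation", n_dz)

        ma_results, failed = _step1(effects, config)
        pooled = pool_rors(ma_results, method=config.tau2_method, ci_method=config.ci_method)

        subgroups: dict[str, SubgroupResult] = {}
        for grouping in config.subgroups:
            labels = subgroup_labels(dataset, grouping)
            n_dropped = sum(1 for val in labels.values() if val is None)
            if n_dropped:
                logger.info("subgroup %s: %d MA(s) outside the dichotomy excluded", grouping, n_dropped)
            try:
                subgroups[grouping] = subgroup_analysis(
                    ma_results, labels, grouping=grouping,
                    method=config.tau2_method, ci_method=config.ci_method,
                )
            except ValueError as err:
                logger.warning("subgroup %s skipped: %s", grouping, err)

        adjusted = {}
        for domain in config.adjust_rob:
            adjusted[domain] = _adjusted_step(effects, dataset.trials, domain, config)

        bundle = ReportBundle(
            dataset=dataset,
            filter_reports=filter_reports,
            effects=effects,
            ma_results=ma_results,
            failed_mas=failed,
            pooled=pooled,
            subgroups=subgroups,
            adjusted=adjusted,
        )
        if write:
            _write_bundle(bundle, out_dir)
        return bundle
    finally:
        if write:
            logging.getLogger("metaepi").removeHandler(handler)
            handler.close()


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    write_results(bundle.filter_reports, out_dir / "filter_report.csv")
    write_results(bundle.effects, out_dir / "effects.csv")
    write_results(bundle.ma_results, out_dir / "ma_results.csv")
    write_results(bundle.pooled, out_dir / "pooled.json")
    for name, sg in bundle.subgroups.items():
        write_results(sg, out_dir / f"subgroup_{name}.json")
    for domain, (results, pooled, _) in bundle.adjusted.items():
        write_results(results, out_dir / f"adjusted_{domain}.csv")
        write_results(pooled, out_dir / f"adjusted_{domain}_pooled.json")
    (out_dir / "summary.txt").write_text(render_summary(bundle), encoding="utf-8")


def _fmt_pooled(p: PooledResult) -> str:
    line = f"ROR {p.ror:.2f} (95% CI {p.ci_low:.2f} to {p.ci_high:.2f}), k={p.k}"
    if p.i2 is not None:
        line += (
            f", I^2={p.i2:.0f}% (95% CI {p.i2_ci_low:.0f} to {p.i2_ci_high:.0f}%),"
            f" tau^2={p.tau2_between:.2f}"
        )
    return line


def render_summary(bundle: ReportBundle) -> str:
    """Plain-text forest-style report of the bundle."""
    lines = ["Two-step ratio-of-odds-ratios analysis", "=" * 40, ""]
    lines.append(f"Meta-analyses analysed: {len(bundle.ma_results)}")
    if bundle.failed_mas:
        lines.append(f"Meta-analyses not estimable: {len(bundle.failed_mas)}")
    lines.append("")
    lines.append("Per-meta-analysis RORs (primary vs secondary/tertiary care)")
    for r in sorted(bundle.ma_results, key=lambda r: r.ma_id):
        lines.append(
            f"  {r.ma_id:>8}  ROR {r.ror:6.2f}  (k_pc={r.k_pc}, k_st={r.k_st},"
            f" tau2_within={r.tau2_within:.3f})"
        )
    lines.append("")
    lines.append("Combined: " + _fmt_pooled(bundle.pooled))
    for name, sg in bundle.subgroups.items():
        lines.append("")
        lines.append(f"Subgroup analysis by {name} (interaction P={sg.p_interaction:.2f})")
        for level, pg in sg.per_group.items():
            lines.append(f"  {level:>20}: " + _fmt_pooled(pg))
    if bundle.adjusted:
        lines.append("")
        lines.append("Risk-of-bias-adjusted combined RORs")
        for domain, (_, pooled, fallbacks) in bundle.adjusted.items():
            note = f" ({len(fallbacks)} MA(s) unadjusted fallback)" if fallbacks else ""
            lines.append(f"  {domain:>34}: " + _fmt_pooled(pooled) + note)
    lines.append("")
    return "\n".join(lines)


def descriptive_summary(dataset: Dataset) -> dict[str, pd.DataFrame]:
    """Descriptive tables by setting and by MA.

    Quartiles use linear interpolation between closest ranks (the default
    inclusive convention), so for {1,2,3,4,5} the IQR is (2, 4).
    """
    trials = dataset.trials

    def _num(series: pd.Series) -> dict[str, float]:
        if len(series) == 0:
            return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan, "min": np.nan, "max": np.nan}
        s = series.astype(float)
        return {
            "n": len(s),
            "median": float(s.median()),
            "q1": float(s.quantile(0.25)),
            "q3": float(s.quantile(0.75)),
            "min": float(s.min()),
            "max": float(s.max()),
        }

    rows = []
    for setting in ("PC", "ST"):
        sub = trials[trials["setting"] == setting]
        rows.append({"group": setting, "variable": "sample_size", **_num(sub["sample_size"])})
        rows.append({"group": setting, "variable": "year", **_num(sub["year"].dropna())})
        rows.append({"group": setting, "variable": "n_centers", **_num(sub["n_centers"].dropna())})
    counts = trials.groupby("ma_id").size() if len(trials) else pd.Series(dtype=int)
    pc_counts = trials[trials["setting"] == "PC"].groupby("ma_id").size() if len(trials) else pd.Series(dtype=int)
    st_counts = trials[trials["setting"] == "ST"].groupby("ma_id").size() if len(trials) else pd.Series(dtype=int)
    rows.append({"group": "MA", "variable": "trials_per_ma", **_num(counts)})
    rows.append({"group": "MA", "variable": "pc_trials_per_ma", **_num(pc_counts)})
    rows.append({"group": "MA", "variable": "st_trials_per_ma", **_num(st_counts)})
    numeric = pd.DataFrame(rows, columns=["group", "variable", "n", "median", "q1", "q3", "min", "max"])

    cat_rows = []
    for col in ("intervention_type", "control_type", "outcome_class"):
        if len(dataset.mas):
            vc = dataset.mas[col].value_counts()
            for level, n in vc.items():
                cat_rows.append(
                    {"variable": col, "level": level, "n": int(n), "percent": 100.0 * n / len(dataset.mas)}
                )
    for setting in ("PC", "ST"):
        sub = trials[trials["setting"] == setting]
        for col in [c for c in trials.columns if c.startswith("rob_")]:
            if len(sub):
                vc = sub[col].value_counts()
                for level, n in vc.items():
                    cat_rows.append(
                        {
                            "variable": f"{col}[{setting}]",
                            "level": level,
                            "n": int(n),
                            "percent": 100.0 * n / len(sub),
                        }
                    )
    categorical = pd.DataFrame(cat_rows, columns=["variable", "level", "n", "percent"])
    return {"numeric": numeric, "categorical": categorical}
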