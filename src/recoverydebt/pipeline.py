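"""Full analysis orchestration: records in, report tables out.

Stages: (1) validate records; (2) select the zero-handling strategy from the
database; (3) compute per-record debt ratios; (4) impute missing sampling
variances within each recovery metric; (5) per metric, fit the null
three-level model, then for each moderator the omnibus Q_M test and the
no-intercept per-category estimates; (6) I^2 on the variance-reporting
subset; (7) recovery-time summaries per reporting cell. Every stage logs
record counts in/out and exclusion reasons. The whole run is deterministic
given the database and configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .debt import RecoveryDebt, StrategyReport
from .meta import ThreeLevelMetaAnalysis, i_squared, impute_variances
from .records import OutcomeMeasure, validate_record


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    method: str = "exponential"  # interpolation between start and end values
    moderators: tuple[str, ...] = ("ecosystem", "disturbance")
    zero_strategy: Optional[int] = None  # None: select from the data
    min_category_effects: int = 2  # categories with fewer effects are set aside

    def digest(self) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "moderators": list(self.moderators),
                "zero_strategy": self.zero_strategy,
                "min_category_effects": self.min_category_effects,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending subset."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class AnalysisReport:
    """Machine-readable tables of a full recovery-debt analysis."""

    pooled: pd.DataFrame  # per-metric null-model estimates
    categories: pd.DataFrame  # per metric x moderator x category estimates
    qm: pd.DataFrame  # omnibus moderator tests
    i2: pd.DataFrame  # heterogeneity on the variance-reporting subset
    recovery_times: pd.DataFrame
    debts: pd.DataFrame  # per-record results
    strategy: Optional[StrategyReport]
    stage_log: list[dict]
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "pooled": self.pooled,
            "categories": self.categories,
            "qm": self.qm,
            "i2": self.i2,
            "recovery_times": self.recovery_times,
            "debts": self.debts,
        }


def recovery_time_summary(
    records: pd.DataFrame | Sequence[OutcomeMeasure],
    grouping: Optional[str] = None,
    t_col: str = "t_years",
    study_col: str = "study_id",
) -> pd.DataFrame:
    """Mean, standard error and median of the recovery time per group.

    ``se`` is sd/sqrt(k); a single-record group reports it as missing.
    Empty groups simply do not appear.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            {
                t_col: [r.t_years for r in records],
                study_col: [r.study_id for r in records],
                **({grouping: [getattr(r, grouping) for r in records]} if grouping else {}),
            }
        )
    if len(records) == 0:
        raise ValueError("recovery_time_summary: no records")
    if grouping is None:
        groups = [("all", records)]
    else:
        groups = list(records.groupby(grouping, observed=True))
    rows = []
    for label, g in groups:
        t = pd.to_numeric(g[t_col]).to_numpy(dtype=float)
        k = t.size
        rows.append(
            {
                "label": label,
                "mean_t": float(np.mean(t)),
                "se_t": float(np.std(t, ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
                "median_t": float(np.median(t)),
                "k": int(k),
                "n_studies": int(g[study_col].nunique()),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(
    db: Sequence[OutcomeMeasure], config: Optional[RunConfig] = None
) -> AnalysisReport:
    """Run the complete analysis over a database of outcome measures."""
    config = config or RunConfig()
    if len(db) == 0:
        raise PipelineError("input", "empty database")
    if config.method not in ("exponential", "linear"):
        raise PipelineError("config", f"unknown method {config.method!r}")
    log: list[dict] = []

    valid = [r for r in db if not validate_record(r)]
    log.append(
        {"stage": "validate", "n_in": len(db), "n_out": len(valid),
         "note": f"{len(db) - len(valid)} invalid records dropped"}
    )
    if not valid:
        raise PipelineError("validate", "no valid records")

    # strategy selection + per-record debts
    debt = RecoveryDebt(method=config.method, zero_strategy=config.zero_strategy)
    try:
        debts = debt.fit_transform(valid)
    except ValueError as e:
        raise PipelineError("zero_strategy", str(e)) from e
    usable = debts[debts["ratio_pct"].notna()].copy()
    log.append(
        {"stage": "debt", "n_in": len(valid), "n_out": len(usable),
         "note": f"{len(debts) - len(usable)} unusable records excluded"}
    )
    if usable.empty:
        raise PipelineError("debt", "no usable records after debt computation")

    effects = usable.rename(columns={"ratio_pct": "effect"})[
        ["outcome_id", "study_id", "metric", "submetric", "ecosystem",
         "disturbance", "effect", "variance", "t_years", "scenario"]
    ]

    pooled_rows, cat_rows, qm_rows, i2_rows, time_rows = [], [], [], [], []
    for metric, sub in effects.groupby("metric", observed=True):
        try:
            sub_i = impute_variances(sub)
        except ValueError as e:
            raise PipelineError("impute", f"metric {metric!r}: {e}") from e

        est = ThreeLevelMetaAnalysis().fit(sub_i)
        pooled_rows.append(
            {"metric": metric, "mean": est.mu_, "ci_low": est.ci_low_,
             "ci_high": est.ci_high_, "k": est.k_, "n_studies": est.n_studies_,
             "tau2_study": est.tau2_study_, "tau2_effect": est.tau2_effect_}
        )

        obs = sub_i[~sub_i["imputed"]]
        if len(obs) >= 2 and (obs["variance"] > 0).all():
            i2_rows.append(
                {"metric": metric,
                 "i2": i_squared(obs["effect"].to_numpy(), obs["variance"].to_numpy()),
                 "k": len(obs)}
            )

        ts = recovery_time_summary(sub_i)
        ts.insert(0, "moderator", "none")
        ts.insert(0, "metric", metric)
        time_rows.append(ts)

        for mod in config.moderators:
            counts = sub_i[mod].value_counts(dropna=True)
            keep = counts[counts >= config.min_category_effects].index
            dropped = sorted(set(counts.index) - set(keep))
            mod_sub = sub_i[sub_i[mod].isin(keep)]
            if len(keep) < 2:
                log.append(
                    {"stage": "moderator", "n_in": len(sub_i), "n_out": 0,
                     "note": f"{metric}/{mod}: <2 usable categories, fit skipped"}
                )
                continue
            if dropped:
                log.append(
                    {"stage": "moderator", "n_in": len(sub_i), "n_out": len(mod_sub),
                     "note": f"{metric}/{mod}: categories set aside (<"
                             f"{config.min_category_effects} effects): {dropped}"}
                )
            try:
                with_int = ThreeLevelMetaAnalysis(moderator=mod, intercept=True).fit(mod_sub)
                no_int = ThreeLevelMetaAnalysis(moderator=mod, intercept=False).fit(mod_sub)
            except ValueError as e:
                raise PipelineError("fit", f"{metric}/{mod}: {e}") from e
            qm_rows.append(
                {"metric": metric, "moderator": mod, "q_m": with_int.q_m_,
                 "df": with_int.q_m_df_, "p": with_int.q_m_p_}
            )
            ce = no_int.category_estimates_.copy()
            ce.insert(0, "moderator", mod)
            ce.insert(0, "metric", metric)
            cat_rows.append(ce)
            tsm = recovery_time_summary(mod_sub, grouping=mod)
            tsm.insert(0, "moderator", mod)
            tsm.insert(0, "metric", metric)
            time_rows.append(tsm)

    report = AnalysisReport(
        pooled=pd.DataFrame(pooled_rows),
        categories=(
            pd.concat(cat_rows, ignore_index=True) if cat_rows
            else pd.DataFrame(columns=["metric", "moderator", "label", "mean",
                                       "ci_low", "ci_high", "k", "n_studies"])
        ),
        qm=pd.DataFrame(qm_rows, columns=["metric", "moderator", "q_m", "df", "p"]),
        i2=pd.DataFrame(i2_rows, columns=["metric", "i2", "k"]),
        recovery_times=pd.concat(time_rows, ignore_index=True),
        debts=debts,
        strategy=debt.strategy_report_,
        stage_log=log,
        metadata={
            "config_digest": config.digest(),
            "method": config.method,
            "zero_strategy": debt.zero_strategy_,
            "n_records_in": len(db),
            "n_records_used": int(len(usable)),
            "scenario_counts": usable["scenario"].value_counts().to_dict(),
        },
    )
    _check_report(report)
    return report


def _check_report(report: AnalysisReport) -> None:
    ok_ci = (report.pooled["ci_low"] <= report.pooled["mean"]).all() and (
        report.pooled["mean"] <= report.pooled["ci_high"]
    ).all()
    if not ok_ci:
        raise PipelineError("report", "pooled CI bounds do not bracket the mean")
    n_scen = sum(report.metadata["scenario_counts"].values())
    if n_scen != report.metadata["n_records_used"]:
        raise PipelineError("report", "scenario counts do not sum to usable records")


def write_report(report: AnalysisReport, outdir) -> list[Path]:
    """Write one CSV per table plus a plain-text summary. Deterministic."""
    from . import io as rd_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in report.tables().items():
        if len(table) == 0:
            continue
        p = outdir / f"{name}.csv"
        rd_io.write_results(table, p)
        written.append(p)
    lines = ["Recovery debt analysis", "======================", ""]
    lines.append(f"method: {report.metadata['method']}  "
                 f"zero strategy: {report.metadata['zero_strategy']}  "
                 f"config: {report.metadata['config_digest']}")
    lines.append(f"records used: {report.metadata['n_records_used']} "
                 f"of {report.metadata['n_records_in']}")
    lines.append(f"scenario counts: {json.dumps(report.metadata['scenario_counts'], sort_keys=True)}")
    lines.append("")
    lines.append("Per-annum recovery debt (percent of reference, 95% CI):")
    for _, row in report.pooled.iterrows():
        lines.append(
            f"  {row['metric']:<10} {row['ci_low']:.0f}-{row['ci_high']:.0f}% "
            f"(mean {row['mean']:.0f}%, k={int(row['k'])}, studies={int(row['n_studies'])})"
        )
    if len(report.i2):
        lines.append("")
        lines.append("I^2 (variance-reporting subset):")
        for _, row in report.i2.iterrows():
            lines.append(f"  {row['metric']:<10} {row['i2']:.2f}% (k={int(row['k'])})")
    if report.strategy is not None:
        lines.append("")
        lines.append(
            f"zero-handling strategy selected: {report.strategy.selected_strategy} "
            f"({'no strategy passed; largest p used' if report.strategy.none_passed else 'p > 0.05'})"
        )
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(summary)
    (outdir / "stage_log.json").write_text(
        json.dumps(report.stage_log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    written.append(outdir / "stage_log.json")
    return written
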