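"""End-to-end validation experiment: simulate -> detect -> summarize -> compare.

One call (or ``actiwear run-all``) reproduces the full study design on a
synthetic cohort: generate subject-days with ground truth, run every
configured non-wear rule plus the diary reference, reduce each subject-day
to wear and intensity minutes, and emit the comparison report (per-rule
means and differences, CCC, kappas, valid-day percentages, Bland-Altman
data) with a manifest carrying the configuration hash and seed.

Non-wear **period counts** reported per day are the *interior* periods —
detected non-wear intervals that do not touch the day boundaries — so that
algorithm counts are commensurable with the diary, whose period count is the
number of daytime removals (the overnight block is off-schedule for both).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .agreement import build_comparison_tables
from .core import MINUTES_PER_DAY, NONWEAR, DaySummary, diary_to_wear_intervals, rescale_intervals
from .intensity import (
    DEFAULT_MIN_DAYS,
    DEFAULT_MIN_WEAR_HOURS,
    DEFAULT_MVPA_THRESHOLD_MIN,
    CutpointSet,
    subject_inclusion,
    summarize_day,
)
from .io import summaries_to_frame
from .nonwear import RULE_NAMES, NonwearRuleConfig, apply_rule
from .simulate import CohortBundle, SimulationConfig, config_from_dict, simulate_cohort

logger = logging.getLogger("actiwear")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rules: tuple[str, ...] = tuple(RULE_NAMES)
    cutpoints: CutpointSet = field(default_factory=CutpointSet)
    axis_mode: str = "vertical"
    min_wear_hours: float = DEFAULT_MIN_WEAR_HOURS
    mvpa_threshold_min: float = DEFAULT_MVPA_THRESHOLD_MIN
    min_days: int = DEFAULT_MIN_DAYS
    n_boot: int = 1000
    seed: int = 0  # analysis-stage randomness (bootstrap CIs)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("rule list must be non-empty")
        unknown = set(self.rules) - set(RULE_NAMES)
        if unknown:
            raise ValueError(f"unknown rules {sorted(unknown)}")
        if self.min_wear_hours <= 0 or self.mvpa_threshold_min <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        cuts = data.pop("cutpoints", {})
        if "rules" in data:
            data["rules"] = tuple(data["rules"])
        return cls(
            simulation=config_from_dict(sim) if isinstance(sim, dict) else sim,
            cutpoints=CutpointSet(**cuts) if isinstance(cuts, dict) else cuts,
            **data,
        )


def interior_period_count(nonwear_minute_intervals) -> int:
    """Detected non-wear periods that do not abut the day boundaries."""
    return sum(
        1
        for iv in nonwear_minute_intervals
        if iv.state == NONWEAR and iv.start_epoch > 0 and iv.end_epoch < MINUTES_PER_DAY
    )


def summarize_cohort(
    bundle: CohortBundle,
    rules: tuple[str, ...] = tuple(RULE_NAMES),
    cutpoints: CutpointSet | None = None,
    axis_mode: str = "vertical",
) -> pd.DataFrame:
    """Per subject-day summaries under every rule plus the diary reference.

    Detection runs on the one-minute grid; band classification on the native
    epoch grid with minute-grid non-wear expanded onto it.
    """
    cutpoints = cutpoints or CutpointSet()
    configs = {r: NonwearRuleConfig.for_rule(r, axis_mode=axis_mode) for r in rules}
    summaries: list[DaySummary] = []
    diaries = {(d.subject_id, d.day_index): d for d in bundle.diaries}
    for series in bundle.series:
        native = series.epoch_seconds
        diary = diaries[(series.subject_id, series.day_index)]
        diary_iv = diary_to_wear_intervals(diary, 60)
        summaries.append(
            summarize_day(
                series,
                rescale_intervals(diary_iv, 60, native),
                cutpoints,
                rule_label="diary",
                nonwear_period_count=len(diary.off_periods),
                axis_mode=axis_mode,
            )
        )
        for rule, config in configs.items():
            _, nonwear, _ = apply_rule(series, config)
            summaries.append(
                summarize_day(
                    series,
                    rescale_intervals(nonwear, 60, native),
                    cutpoints,
                    rule_label=rule,
                    nonwear_period_count=interior_period_count(nonwear),
                    axis_mode=axis_mode,
                )
            )
    return summaries_to_frame(summaries)


def apply_subject_inclusion(summaries: pd.DataFrame, min_days: int = DEFAULT_MIN_DAYS) -> pd.DataFrame:
    """Drop subjects with fewer than ``min_days`` recorded diary days,
    logging each exclusion."""
    kept = []
    for subject, grp in summaries[summaries["rule"] == "diary"].groupby("subject_id"):
        if grp["day"].nunique() >= min_days:
            kept.append(subject)
        else:
            logger.info(
                "excluding subject %s: only %d recorded day(s)", subject, grp["day"].nunique()
            )
    return summaries[summaries["subject_id"].isin(kept)].reset_index(drop=True)


def run_validation_experiment(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Execute every stage and return the report bundle keyed by artifact name.

    Idempotent for a fixed configuration: the same config and seeds yield
    byte-identical tables.  With ``out_dir`` set, per-stage artifacts and a
    run manifest (config hash + seeds) are written as delimited text.
    """
    logger.info("simulating cohort: %d subjects x %d days",
                config.simulation.n_subjects, config.simulation.days_per_subject)
    bundle = simulate_cohort(config.simulation)
    logger.info("summarizing %d subject-days under %d rules + diary",
                len(bundle.series), len(config.rules))
    summaries = summarize_cohort(bundle, config.rules, config.cutpoints, config.axis_mode)
    summaries = apply_subject_inclusion(summaries, config.min_days)
    logger.info("building comparison tables")
    tables = build_comparison_tables(
        summaries,
        rules=list(config.rules),
        seed=config.seed,
        n_boot=config.n_boot,
        min_wear_hours=config.min_wear_hours,
        mvpa_threshold_min=config.mvpa_threshold_min,
    )
    report = {"summaries": summaries, **tables}
    if out_dir is not None:
        write_report(report, config, out_dir)
    return report


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_plain(asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_report(report: dict[str, pd.DataFrame], config: PipelineConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in report.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "config": _plain(asdict(config)),
        "config_hash": config_hash(config),
        "simulation_seed": config.simulation.seed,
        "analysis_seed": config.seed,
        "artifacts": sorted(f"{name}.csv" for name in report),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("report written to %s", out)
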