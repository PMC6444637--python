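"""Intensity classification and per-day data-reduction rules.

Counts per 15-s epoch are partitioned into sedentary / light / moderate /
vigorous bands by youth cut-points (defaults: 0–180, 181–757, 758–1112,
>1112 counts per 15 s, vertical axis).  Day summaries count in-wear minutes
per band under a given non-wear rule; downstream filters apply the 10-h
valid-day rule, the 60-min/day MVPA guideline, and the >= 3 recorded days
subject-inclusion criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NONWEAR, DaySummary, EpochSeries, WearInterval, intervals_to_mask

SEDENTARY, LIGHT, MODERATE, VIGOROUS = 0, 1, 2, 3
BAND_NAMES = ("sedentary", "light", "moderate", "vigorous")

DEFAULT_MIN_WEAR_HOURS = 10
DEFAULT_MVPA_THRESHOLD_MIN = 60
DEFAULT_MIN_DAYS = 3


@dataclass(frozen=True)
class CutpointSet:
    """Inclusive upper band bounds in counts per 15 s; vigorous is above
    ``moderate_max``."""

    sedentary_max: int = 180
    light_max: int = 757
    moderate_max: int = 1112

    def __post_init__(self) -> None:
        if not 0 <= self.sedentary_max < self.light_max < self.moderate_max:
            raise ValueError("cut-points must satisfy 0 <= sed < light < moderate")

    @property
    def bounds(self) -> tuple[int, int, int]:
        return (self.sedentary_max, self.light_max, self.moderate_max)


def classify_epoch(count_15s: float, cutpoints: CutpointSet | None = None) -> int:
    """Band code for a single 15-s epoch count (0=sedentary … 3=vigorous)."""
    if count_15s < 0:
        raise ValueError("counts must be non-negative")
    cutpoints = cutpoints or CutpointSet()
    return int(np.searchsorted(cutpoints.bounds, count_15s, side="left"))


def classify_epochs(counts: np.ndarray, cutpoints: CutpointSet | None = None) -> np.ndarray:
    """Vectorized band codes for a counts-per-15-s array."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    cutpoints = cutpoints or CutpointSet()
    return np.searchsorted(cutpoints.bounds, counts, side="left")


def summarize_day(
    series: EpochSeries,
    nonwear: list[WearInterval],
    cutpoints: CutpointSet | None = None,
    rule_label: str = "",
    nonwear_period_count: int | None = None,
    axis_mode: str = "vertical",
) -> DaySummary:
    """Tally in-wear minutes per intensity band for one subject-day.

    ``nonwear`` must be expressed on the same epoch grid as ``series`` (use
    :func:`actiwear.core.rescale_intervals` after minute-grid detection).
    Minutes are multiples of one epoch (0.25 min at 15 s); no rounding.
    """
    cutpoints = cutpoints or CutpointSet()
    try:
        nonwear_mask = intervals_to_mask(nonwear, series.n_epochs, state=NONWEAR)
    except ValueError as exc:
        raise ValueError(f"non-wear intervals do not fit the series grid: {exc}") from exc
    minute_factor = series.epoch_seconds / 60.0
    wear_counts = series.axis_counts(axis_mode)[~nonwear_mask]
    bands = classify_epochs(wear_counts, cutpoints)
    tallies = np.bincount(bands, minlength=4)
    if nonwear_period_count is None:
        nonwear_period_count = sum(1 for iv in nonwear if iv.state == NONWEAR)
    return DaySummary(
        subject_id=series.subject_id,
        day_index=series.day_index,
        rule=rule_label,
        wear_min=len(wear_counts) * minute_factor,
        sedentary_min=tallies[SEDENTARY] * minute_factor,
        light_min=tallies[LIGHT] * minute_factor,
        moderate_min=tallies[MODERATE] * minute_factor,
        vigorous_min=tallies[VIGOROUS] * minute_factor,
        nonwear_period_count=nonwear_period_count,
    )


def is_valid_day(summary: DaySummary, min_wear_hours: float = DEFAULT_MIN_WEAR_HOURS) -> bool:
    """True iff the day reaches the minimum wearing time (default 10 h)."""
    return summary.wear_min >= min_wear_hours * 60


def meets_mvpa_guideline(
    summary: DaySummary, threshold_min: float = DEFAULT_MVPA_THRESHOLD_MIN
) -> bool:
    """True iff the day reaches the MVPA recommendation (default 60 min)."""
    return summary.mvpa_min >= threshold_min


def subject_inclusion(summaries: list[DaySummary], min_days: int = DEFAULT_MIN_DAYS) -> bool:
    """True iff the subject recorded at least ``min_days`` days."""
    days = {s.day_index for s in summaries}
    return len(days) >= min_days
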