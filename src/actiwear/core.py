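"""Epoch-level activity-count series, wear intervals, and non-wear log diaries.

Hip-worn accelerometers integrate movement into "counts" over fixed epochs
(1, 15, or 60 s here).  Everything downstream — non-wear detection, intensity
classification, day summaries — operates on these per-day series, on half-open
epoch intervals labelled wear/non-wear, and on the participant's log diary
(wake/bed and device on/off clock times, recorded to the minute), which serves
as the reference wear schedule.

Conventions: epochs are 0-based; intervals are half-open ``[start, end)``;
a series never spans midnight (one calendar day per series); clock times are
minutes past midnight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MINUTES_PER_DAY = 1440
SECONDS_PER_DAY = 86400

WEAR = "wear"
NONWEAR = "nonwear"


class ParseError(ValueError):
    """A delimited input file violates the format or a data invariant."""


def _as_count_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{name} must be numeric")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative counts")
    return arr.astype(np.int64)


@dataclass
class EpochSeries:
    """One subject-day of activity counts on a uniform epoch grid.

    Parameters
    ----------
    subject_id : str
        Opaque participant identifier.
    day_index : int
        1-based day of recording.
    start_clock : int
        Minutes past midnight of the first epoch (0 for a full-day trace).
    epoch_seconds : int
        Seconds per epoch; must divide 60.
    counts_vertical : array-like of int
        Vertical-axis (x) counts per epoch.
    counts_ap, counts_ml : array-like of int, optional
        Anteroposterior (y) and mediolateral (z) axes.
    """

    subject_id: str
    day_index: int
    start_clock: int
    epoch_seconds: int
    counts_vertical: np.ndarray
    counts_ap: np.ndarray | None = None
    counts_ml: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.epoch_seconds not in (1, 2, 3, 4, 5, 6, 10, 12, 15, 20, 30, 60):
            raise ValueError(f"epoch_seconds must divide 60, got {self.epoch_seconds}")
        self.counts_vertical = _as_count_array(self.counts_vertical, "counts_vertical")
        n = len(self.counts_vertical)
        for name in ("counts_ap", "counts_ml"):
            value = getattr(self, name)
            if value is not None:
                value = _as_count_array(value, name)
                if len(value) != n:
                    raise ValueError(f"{name} length {len(value)} != vertical length {n}")
                setattr(self, name, value)
        if self.start_clock < 0 or self.start_clock >= MINUTES_PER_DAY:
            raise ValueError("start_clock must lie within the day")
        if self.start_clock * 60 + n * self.epoch_seconds > SECONDS_PER_DAY:
            raise ValueError("series extends past midnight")
        if self.day_index < 1:
            raise ValueError("day_index is 1-based")

    @property
    def n_epochs(self) -> int:
        return len(self.counts_vertical)

    @property
    def duration_minutes(self) -> float:
        return self.n_epochs * self.epoch_seconds / 60.0

    @property
    def has_triaxial(self) -> bool:
        return self.counts_ap is not None and self.counts_ml is not None

    def axis_counts(self, axis_mode: str = "vertical") -> np.ndarray:
        """Per-epoch counts for the requested axis selection.

        ``vertical`` returns the x axis; ``vector_magnitude`` (or ``vm``)
        returns the rounded Euclidean magnitude across all three axes.
        """
        if axis_mode == "vertical":
            return self.counts_vertical
        if axis_mode in ("vector_magnitude", "vm"):
            return np.rint(vector_magnitude(self)).astype(np.int64)
        raise ValueError(f"unknown axis_mode {axis_mode!r}")


def reintegrate(series: EpochSeries, target_epoch_seconds: int) -> EpochSeries:
    """Re-integrate a series onto a coarser epoch grid by block summation.

    Each output epoch is the sum of the corresponding block of input epochs,
    per axis, so total counts are conserved.  A trailing partial block is
    dropped rather than padded (padding would fabricate counts).
    """
    if 60 % target_epoch_seconds != 0:
        raise ValueError(f"target epoch {target_epoch_seconds}s must divide 60")
    if target_epoch_seconds % series.epoch_seconds != 0:
        raise ValueError(
            f"target epoch {target_epoch_seconds}s is not a multiple of the "
            f"native epoch {series.epoch_seconds}s"
        )
    factor = target_epoch_seconds // series.epoch_seconds
    if factor == 1:
        return replace(series)

    def block_sum(arr: np.ndarray | None) -> np.ndarray | None:
        if arr is None:
            return None
        n_blocks = len(arr) // factor
        return arr[: n_blocks * factor].reshape(n_blocks, factor).sum(axis=1)

    return EpochSeries(
        subject_id=series.subject_id,
        day_index=series.day_index,
        start_clock=series.start_clock,
        epoch_seconds=target_epoch_seconds,
        counts_vertical=block_sum(series.counts_vertical),
        counts_ap=block_sum(series.counts_ap),
        counts_ml=block_sum(series.counts_ml),
    )


def vector_magnitude(series: EpochSeries) -> np.ndarray:
    """Per-epoch vector magnitude sqrt(x² + y² + z²) across the three axes."""
    if not series.has_triaxial:
        raise ValueError("vector magnitude requires all three axes")
    x = series.counts_vertical.astype(float)
    y = series.counts_ap.astype(float)
    z = series.counts_ml.astype(float)
    return np.sqrt(x * x + y * y + z * z)


@dataclass(frozen=True)
class WearInterval:
    """Half-open epoch interval ``[start_epoch, end_epoch)`` labelled wear or
    non-wear, with the rule (or ``"diary"``) that produced it."""

    start_epoch: int
    end_epoch: int
    state: str
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start_epoch < self.end_epoch):
            raise ValueError(
                f"invalid interval [{self.start_epoch}, {self.end_epoch})"
            )
        if self.state not in (WEAR, NONWEAR):
            raise ValueError(f"state must be {WEAR!r} or {NONWEAR!r}")

    @property
    def length(self) -> int:
        return self.end_epoch - self.start_epoch


def validate_interval_set(intervals: list[WearInterval]) -> None:
    """Check that intervals of one labelled set are sorted and disjoint."""
    for prev, cur in zip(intervals, intervals[1:]):
        if cur.start_epoch < prev.end_epoch:
            raise ValueError("intervals overlap or are unsorted")


def intervals_to_mask(
    intervals: list[WearInterval], n_epochs: int, state: str = NONWEAR
) -> np.ndarray:
    """Boolean mask of epochs covered by intervals of the given state."""
    mask = np.zeros(n_epochs, dtype=bool)
    for iv in intervals:
        if iv.state != state:
            continue
        if iv.end_epoch > n_epochs:
            raise ValueError(
                f"interval end {iv.end_epoch} exceeds series length {n_epochs}"
            )
        mask[iv.start_epoch : iv.end_epoch] = True
    return mask


def mask_to_intervals(mask: np.ndarray, state: str, source: str = "") -> list[WearInterval]:
    """Maximal runs of True in ``mask`` as intervals of the given state."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [WearInterval(int(s), int(e), state, source) for s, e in zip(starts, ends)]


def complement_intervals(
    intervals: list[WearInterval], n_epochs: int, state: str, source: str = ""
) -> list[WearInterval]:
    """Intervals of ``state`` covering every epoch not covered by ``intervals``."""
    covered = np.zeros(n_epochs, dtype=bool)
    for iv in intervals:
        covered[iv.start_epoch : iv.end_epoch] = True
    return mask_to_intervals(~covered, state, source)


def rescale_intervals(
    intervals: list[WearInterval], from_epoch_seconds: int, to_epoch_seconds: int
) -> list[WearInterval]:
    """Map intervals between epoch grids by an exact integer factor.

    Typical use: non-wear detected on the 60-s grid expanded onto the 15-s
    classification grid (factor 4).
    """
    if from_epoch_seconds % to_epoch_seconds != 0:
        raise ValueError("grids are not related by an integer factor")
    factor = from_epoch_seconds // to_epoch_seconds
    if factor == 1:
        return list(intervals)
    return [
        WearInterval(iv.start_epoch * factor, iv.end_epoch * factor, iv.state, iv.source)
        for iv in intervals
    ]


@dataclass
class DiaryRecord:
    """One subject-day of the non-wear log diary.

    Wake/bed times and any device off/on times, all whole minutes past
    midnight.  Off periods falling partly outside ``[wake, bed)`` are clipped
    with a warning; overlapping periods are merged.
    """

    subject_id: str
    day_index: int
    wake_time: int
    bed_time: int
    off_periods: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in (self.wake_time, self.bed_time):
            if not (isinstance(t, (int, np.integer)) and 0 <= t <= MINUTES_PER_DAY):
                raise ValueError("diary times must be whole minutes within the day")
        if not self.wake_time < self.bed_time:
            raise ValueError("wake_time must precede bed_time")
        normalized: list[tuple[int, int]] = []
        for off, on in sorted(self.off_periods):
            if not (
                isinstance(off, (int, np.integer)) and isinstance(on, (int, np.integer))
            ):
                raise ValueError("off periods must be whole minutes")
            if off >= on:
                raise ValueError(f"off period ({off}, {on}) has off_time >= on_time")
            clipped = (max(int(off), self.wake_time), min(int(on), self.bed_time))
            if (clipped[0], clipped[1]) != (int(off), int(on)):
                warnings.warn(
                    f"off period ({off}, {on}) clipped to wear window "
                    f"[{self.wake_time}, {self.bed_time}) for subject "
                    f"{self.subject_id} day {self.day_index}",
                    stacklevel=2,
                )
            if clipped[0] >= clipped[1]:
                continue
            if normalized and clipped[0] <= normalized[-1][1]:
                normalized[-1] = (normalized[-1][0], max(normalized[-1][1], clipped[1]))
            else:
                normalized.append(clipped)
        if len(normalized) > 5:
            raise ValueError("more than 5 off periods in one day")
        self.off_periods = normalized

    @property
    def wear_minutes(self) -> int:
        """Diary wear time: bed − wake minus the summed off-period durations."""
        off = sum(on - off for off, on in self.off_periods)
        return self.bed_time - self.wake_time - off


def diary_to_wear_intervals(diary: DiaryRecord, epoch_seconds: int) -> list[WearInterval]:
    """Reference wear schedule as epoch intervals over the full day.

    Wear is exactly ``[wake, bed)`` minus the off periods; everything else in
    the day — overnight time and the off periods themselves — is non-wear
    (the device is removed at night by protocol).
    """
    if 60 % epoch_seconds != 0:
        raise ValueError("epoch_seconds must divide 60")
    per_min = 60 // epoch_seconds
    minute_wear = np.zeros(MINUTES_PER_DAY, dtype=bool)
    minute_wear[diary.wake_time : diary.bed_time] = True
    for off, on in diary.off_periods:
        minute_wear[off:on] = False
    epoch_wear = np.repeat(minute_wear, per_min)
    intervals = mask_to_intervals(epoch_wear, WEAR, "diary")
    intervals += mask_to_intervals(~epoch_wear, NONWEAR, "diary")
    return sorted(intervals, key=lambda iv: iv.start_epoch)


@dataclass
class DaySummary:
    """Per subject-day wear minutes and minutes per intensity band under one
    non-wear rule; the unit of every agreement analysis."""

    subject_id: str
    day_index: int
    rule: str
    wear_min: float
    sedentary_min: float
    light_min: float
    moderate_min: float
    vigorous_min: float
    nonwear_period_count: int

    def __post_init__(self) -> None:
        bands = (self.sedentary_min, self.light_min, self.moderate_min, self.vigorous_min)
        if any(v < 0 for v in bands) or self.wear_min < 0:
            raise ValueError("minutes must be non-negative")
        if self.wear_min > MINUTES_PER_DAY:
            raise ValueError("wear_min exceeds a day")
        if abs(sum(bands) - self.wear_min) > 1e-9:
            raise ValueError("band minutes do not sum to wear minutes")
        if self.nonwear_period_count < 0:
            raise ValueError("nonwear_period_count must be non-negative")

    @property
    def mvpa_min(self) -> float:
        return self.moderate_min + self.vigorous_min
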