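"""Non-wear time detection on counts-per-minute traces.

Seven published rules are implemented, all on the one-minute epoch grid:

* **fixed10 … fixed60** — a non-wear period is any maximal run of at least
  10/15/20/30/60 consecutive zero-count minutes.
* **troiano** — at least 60 min of zeros, tolerating interruption runs of at
  most 2 consecutive minutes whose counts stay below a ceiling (100 cpm by
  default); a minute at or above the ceiling, or a third consecutive nonzero
  minute, breaks the span.
* **choi** — at least 90 min of zeros, where interruption runs of at most
  2 consecutive nonzero minutes (any magnitude) are absorbed only when
  flanked by at least 30 consecutive zero minutes on both sides.

A qualifying span always starts and ends with zero minutes: an interruption
interrupts zeros on both sides, never the edge of a span.  Tolerated
interruption minutes inside an accepted span are counted as non-wear (they
lie inside the non-wear interval).  Runs touching the start or end of the
recorded day qualify on their within-day length; there is no cross-midnight
continuation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    NONWEAR,
    WEAR,
    EpochSeries,
    WearInterval,
    complement_intervals,
    mask_to_intervals,
    reintegrate,
)

FIXED_WINDOWS = {
    "fixed10": 10,
    "fixed15": 15,
    "fixed20": 20,
    "fixed30": 30,
    "fixed60": 60,
}
RULE_NAMES = list(FIXED_WINDOWS) + ["troiano", "choi"]

TROIANO_WINDOW_MIN = 60
TROIANO_COUNT_CEILING = 100
CHOI_WINDOW_MIN = 90
CHOI_FLANK_ZERO_MIN = 30
MAX_INTERRUPTION_MIN = 2


@dataclass(frozen=True)
class NonwearRuleConfig:
    """Parameterization of one detection rule.

    ``interruption_mode`` applies to the Troiano rule only: ``"consecutive"``
    bounds each interruption run at ``max_interruption_min`` consecutive
    minutes (several runs may occur in one span); ``"total"`` bounds the total
    interruption minutes per span instead.
    """

    rule_name: str
    window_min: int
    max_interruption_min: int = 0
    interruption_count_ceiling: int | None = None
    flank_zero_min: int = 0
    axis_mode: str = "vertical"
    interruption_mode: str = "consecutive"

    def __post_init__(self) -> None:
        if self.window_min <= 0:
            raise ValueError("window_min must be positive")
        if self.max_interruption_min < 0 or self.flank_zero_min < 0:
            raise ValueError("interruption and flank lengths must be >= 0")
        if self.rule_name in FIXED_WINDOWS and self.max_interruption_min != 0:
            raise ValueError("fixed rules admit no interruptions")
        if self.interruption_mode not in ("consecutive", "total"):
            raise ValueError("interruption_mode must be 'consecutive' or 'total'")

    @classmethod
    def for_rule(cls, rule_name: str, axis_mode: str = "vertical") -> "NonwearRuleConfig":
        """Default configuration for a named rule."""
        if rule_name in FIXED_WINDOWS:
            return cls(rule_name, FIXED_WINDOWS[rule_name], axis_mode=axis_mode)
        if rule_name == "troiano":
            return cls(
                rule_name,
                TROIANO_WINDOW_MIN,
                max_interruption_min=MAX_INTERRUPTION_MIN,
                interruption_count_ceiling=TROIANO_COUNT_CEILING,
                axis_mode=axis_mode,
            )
        if rule_name == "choi":
            return cls(
                rule_name,
                CHOI_WINDOW_MIN,
                max_interruption_min=MAX_INTERRUPTION_MIN,
                flank_zero_min=CHOI_FLANK_ZERO_MIN,
                axis_mode=axis_mode,
            )
        raise ValueError(f"unknown rule {rule_name!r}; expected one of {RULE_NAMES}")


def _as_cpm(cpm) -> np.ndarray:
    arr = np.asarray(cpm)
    if arr.ndim != 1:
        raise ValueError("cpm must be one-dimensional")
    if np.any(arr < 0):
        raise ValueError("cpm contains negative counts")
    return arr


@dataclass(frozen=True)
class _Run:
    start: int
    end: int
    is_zero: bool
    max_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _runs(cpm: np.ndarray) -> list[_Run]:
    """Run-length encode a trace into maximal zero / nonzero runs."""
    if len(cpm) == 0:
        return []
    nonzero = cpm > 0
    edges = np.flatnonzero(np.diff(nonzero.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(cpm)]))
    return [
        _Run(int(s), int(e), not nonzero[s], int(cpm[s:e].max()))
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


def detect_fixed_window(cpm, window_min: int, source: str | None = None) -> list[WearInterval]:
    """Maximal runs of consecutive zero minutes of length >= ``window_min``."""
    cpm = _as_cpm(cpm)
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    source = source or f"fixed{window_min}"
    return [
        WearInterval(r.start, r.end, NONWEAR, source)
        for r in _runs(cpm)
        if r.is_zero and r.length >= window_min
    ]


def _merge_spans(runs: list[_Run], join_ok, window_min: int) -> list[tuple[int, int]]:
    """Greedily chain zero runs across qualifying nonzero runs; keep spans of
    total length >= ``window_min``.  Merging is local, so chained spans are
    maximal."""
    spans: list[tuple[int, int]] = []
    i = 0
    while i < len(runs):
        if not runs[i].is_zero:
            i += 1
            continue
        start, end = runs[i].start, runs[i].end
        j = i
        while j + 2 < len(runs) and runs[j + 2].is_zero and join_ok(
            runs[j], runs[j + 1], runs[j + 2]
        ):
            end = runs[j + 2].end
            j += 2
        if end - start >= window_min:
            spans.append((start, end))
        i = j + 1
    return spans


def _detect_troiano_total(cpm: np.ndarray, config: NonwearRuleConfig) -> np.ndarray:
    """Union of valid spans under the total-interruption-budget variant,
    via a sliding window over minute positions."""
    n = len(cpm)
    ceiling = config.interruption_count_ceiling
    budget = config.max_interruption_min
    nz = cpm > 0
    hard = cpm >= ceiling
    nonwear = np.zeros(n, dtype=bool)
    r = 0
    cnt = 0
    for left in range(n):
        if r <= left:
            r, cnt = left, 0
        while r < n and not hard[r] and cnt + int(nz[r]) <= budget:
            cnt += int(nz[r])
            r += 1
        if not nz[left]:
            end = r
            while end > left and nz[end - 1]:
                end -= 1
            if end - left >= config.window_min:
                nonwear[left:end] = True
        if r > left and nz[left]:
            cnt -= 1
    return nonwear


def detect_troiano(cpm, config: NonwearRuleConfig | None = None) -> list[WearInterval]:
    """Troiano non-wear: >= 60 min of zeros with a 2-min low-count allowance."""
    cpm = _as_cpm(cpm)
    config = config or NonwearRuleConfig.for_rule("troiano")
    ceiling = config.interruption_count_ceiling
    if ceiling is None:
        raise ValueError("troiano requires an interruption count ceiling")
    if config.interruption_mode == "total":
        mask = _detect_troiano_total(cpm, config)
        return mask_to_intervals(mask, NONWEAR, "troiano")

    def join_ok(z1: _Run, nz: _Run, z2: _Run) -> bool:
        return nz.length <= config.max_interruption_min and nz.max_count < ceiling

    spans = _merge_spans(_runs(cpm), join_ok, config.window_min)
    return [WearInterval(s, e, NONWEAR, "troiano") for s, e in spans]


def detect_choi(cpm, config: NonwearRuleConfig | None = None) -> list[WearInterval]:
    """Choi non-wear: >= 90 min of zeros; 2-min interruptions absorbed only
    between 30-min zero flanks."""
    cpm = _as_cpm(cpm)
    config = config or NonwearRuleConfig.for_rule("choi")
    flank = config.flank_zero_min

    def join_ok(z1: _Run, nz: _Run, z2: _Run) -> bool:
        return (
            nz.length <= config.max_interruption_min
            and z1.length >= flank
            and z2.length >= flank
        )

    spans = _merge_spans(_runs(cpm), join_ok, config.window_min)
    return [WearInterval(s, e, NONWEAR, "choi") for s, e in spans]


def detect(cpm, config: NonwearRuleConfig) -> list[WearInterval]:
    """Dispatch a counts-per-minute trace to the configured rule."""
    if config.rule_name in FIXED_WINDOWS:
        return detect_fixed_window(cpm, config.window_min, source=config.rule_name)
    if config.rule_name == "troiano":
        return detect_troiano(cpm, config)
    if config.rule_name == "choi":
        return detect_choi(cpm, config)
    raise ValueError(f"unknown rule {config.rule_name!r}")


def apply_rule(
    series: EpochSeries, config: NonwearRuleConfig
) -> tuple[list[WearInterval], list[WearInterval], int]:
    """Run one rule on a subject-day.

    The series is re-integrated to the one-minute grid if needed and the axis
    selected per ``config.axis_mode``.  Returns ``(wear intervals, non-wear
    intervals, non-wear period count)`` on the minute grid; wear is the
    complement of non-wear within the recorded day.
    """
    if series.epoch_seconds != 60:
        if 60 % series.epoch_seconds != 0:
            raise ValueError("series epoch does not divide 60 s")
        series = reintegrate(series, 60)
    cpm = series.axis_counts(config.axis_mode)
    nonwear = detect(cpm, config)
    wear = complement_intervals(nonwear, series.n_epochs, WEAR, config.rule_name)
    return wear, nonwear, len(nonwear)
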