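"""Synthetic validation cohorts with known wear/non-wear ground truth.

The generator emulates a 4-day free-living protocol in 10-17-year-olds
wearing a hip accelerometer: a diurnal wear schedule (device off overnight),
0-3 daytime removals per day (showers, swimming, contact sports), and an
intensity-structured count stream produced by a semi-Markov bout model over
five states — motionless sedentary (exact zeros: the state that non-wear
rules confuse with removal), fidgeting sedentary, light, moderate, and
vigorous.  Dwell times are lognormal so long zero runs arise with realistic
autocorrelation; per-state counts are drawn uniformly within the intensity
band ranges of the cut-point set in force.  Optional 1-2-min handling
artifacts ("spikes") can be injected inside true non-wear, and the diary can
carry minute-level reporting noise.

Every subject-day stream is keyed by ``(seed, subject, day)``, so a cohort
is fully reproducible and per-subject regeneration is stable under changes
of cohort size.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .core import (
    MINUTES_PER_DAY,
    NONWEAR,
    WEAR,
    DiaryRecord,
    EpochSeries,
    WearInterval,
    mask_to_intervals,
)
from . import io as awio

STILL, FIDGET, LIGHT_STATE, MODERATE_STATE, VIGOROUS_STATE = range(5)
STATE_NAMES = ("still", "fidget", "light", "moderate", "vigorous")
NONWEAR_STATE = -1

# counts per 15-s epoch emitted in each state (inclusive ranges); still is
# exactly zero, the remaining ranges coincide with the default cut-point bands
STATE_COUNT_RANGES = {
    STILL: (0, 0),
    FIDGET: (1, 180),
    LIGHT_STATE: (181, 757),
    MODERATE_STATE: (758, 1112),
    VIGOROUS_STATE: (1113, 3000),
}


class SimulationError(RuntimeError):
    """Raised when a feasible wear schedule cannot be sampled."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the validation protocol being emulated: 77 participants,
    4 recording days each, 15-s epochs, device on ~08:10 and off ~21:05
    (truncated normals, whole minutes, giving ~12.5 h of scheduled wear, about
    730 wear min/day after removals), removal-count probabilities over {0,1,2,3}
    matching the diary-reported frequencies, lognormal removal durations
    (median ~40 min, minimum 5), and a bout mix that puts roughly 70% of wear
    time in sedentary behaviour and ~8% in MVPA.
    """

    n_subjects: int = 77
    days_per_subject: int = 4
    epoch_seconds: int = 15
    seed: int = 0

    wake_mean: float = 490.0
    wake_sd: float = 40.0
    wake_min: float = 400.0
    wake_max: float = 600.0
    bed_mean: float = 1265.0
    bed_sd: float = 40.0
    bed_min: float = 1170.0
    bed_max: float = 1380.0

    removal_probs: tuple[float, ...] = (0.507, 0.425, 0.052, 0.016)
    removal_median_min: float = 40.0
    removal_sigma: float = 0.6
    removal_min_min: float = 5.0
    removal_max_min: float = 240.0
    removal_gap_min: int = 30

    # semi-Markov bout model: lognormal dwell (median minutes, log-sd, bounds)
    stillness_minutes: float = 10.0
    still_sigma: float = 0.5
    still_dwell_min: float = 1.0
    still_dwell_max: float = 45.0
    dwell_params: dict = field(
        default_factory=lambda: {
            FIDGET: (8.0, 0.6, 1.0, 60.0),
            LIGHT_STATE: (5.0, 0.6, 0.5, 30.0),
            MODERATE_STATE: (3.0, 0.5, 0.5, 15.0),
            VIGOROUS_STATE: (1.5, 0.5, 0.25, 8.0),
        }
    )
    transitions: tuple[tuple[float, ...], ...] = (
        (0.00, 0.60, 0.30, 0.08, 0.02),
        (0.45, 0.00, 0.40, 0.12, 0.03),
        (0.25, 0.40, 0.00, 0.25, 0.10),
        (0.10, 0.20, 0.50, 0.00, 0.20),
        (0.05, 0.15, 0.30, 0.50, 0.00),
    )
    initial_probs: tuple[float, ...] = (0.30, 0.30, 0.25, 0.10, 0.05)

    nonwear_spike_rate: float = 0.0  # probability per non-wear hour of an artifact
    spike_epoch_count_max: int = 24  # keeps spike minutes below 100 cpm
    diary_noise_sd: float = 0.0
    triaxial: bool = True
    max_schedule_retries: int = 200

    def __post_init__(self) -> None:
        if abs(sum(self.removal_probs) - 1) > 1e-9:
            raise ValueError("removal_probs must sum to 1")
        for row in self.transitions:
            if abs(sum(row) - 1) > 1e-9:
                raise ValueError("transition rows must sum to 1")
            if any(p < 0 or p > 1 for p in row):
                raise ValueError("transition probabilities must lie in [0, 1]")
        if abs(sum(self.initial_probs) - 1) > 1e-9:
            raise ValueError("initial_probs must sum to 1")
        if self.stillness_minutes <= 0 or self.still_dwell_min <= 0:
            raise ValueError("dwell scales must be positive")
        if not (0 <= self.nonwear_spike_rate <= 1):
            raise ValueError("nonwear_spike_rate must lie in [0, 1]")
        if 60 % self.epoch_seconds != 0:
            raise ValueError("epoch_seconds must divide 60")

    @classmethod
    def easy_regime(cls, **overrides) -> "SimulationConfig":
        """Exact-recovery conditions: every removal lasts >= 90 min, bed is
        early enough that the evening off-body segment also reaches 90 min,
        no motionless-sedentary state (all wear minutes are nonzero), and no
        handling artifacts — so every rule, including the 10-min window and
        Choi, sees exactly the true non-wear."""
        no_still = tuple(
            tuple(0.0 if j == STILL else row[j] / (1 - row[STILL]) for j in range(5))
            for row in cls().transitions
        )
        params = dict(
            removal_median_min=110.0,
            removal_sigma=0.2,
            removal_min_min=90.0,
            removal_max_min=240.0,
            removal_probs=(0.35, 0.45, 0.15, 0.05),
            bed_max=1344.0,
            transitions=no_still,
            initial_probs=(0.0, 0.45, 0.35, 0.13, 0.07),
            nonwear_spike_rate=0.0,
            diary_noise_sd=0.0,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def hard_regime(cls, **overrides) -> "SimulationConfig":
        """Misclassification-prone conditions: long motionless sedentary
        bouts (lognormal dwell, median 25 min, truncated to 12-45 min) that
        short zero-window rules confuse with removals."""
        sticky = (
            (0.00, 0.60, 0.28, 0.09, 0.03),
            (0.60, 0.00, 0.28, 0.09, 0.03),
            (0.40, 0.30, 0.00, 0.20, 0.10),
            (0.15, 0.20, 0.45, 0.00, 0.20),
            (0.05, 0.15, 0.30, 0.50, 0.00),
        )
        params = dict(
            stillness_minutes=25.0,
            still_sigma=0.35,
            still_dwell_min=12.0,
            still_dwell_max=45.0,
            transitions=sticky,
            initial_probs=(0.35, 0.25, 0.25, 0.10, 0.05),
        )
        params.update(overrides)
        return cls(**params)

    def state_dwell(self, state: int) -> tuple[float, float, float, float]:
        if state == STILL:
            return (
                self.stillness_minutes,
                self.still_sigma,
                self.still_dwell_min,
                self.still_dwell_max,
            )
        return self.dwell_params[state]


@dataclass
class GroundTruth:
    """The simulator's true wear schedule and per-epoch intensity state."""

    subject_id: str
    day_index: int
    wear_intervals: list[WearInterval]  # minute grid
    states: np.ndarray  # per native epoch; NONWEAR_STATE outside wear
    removal_count: int

    @property
    def wear_minutes(self) -> int:
        return sum(iv.length for iv in self.wear_intervals if iv.state == WEAR)

    @property
    def nonwear_minutes(self) -> int:
        return MINUTES_PER_DAY - self.wear_minutes

    def band_minutes(self, epoch_seconds: int) -> dict[str, float]:
        """True minutes per intensity band (still+fidget are both sedentary)."""
        factor = epoch_seconds / 60.0
        tallies = {name: 0.0 for name in ("sedentary", "light", "moderate", "vigorous")}
        for s in self.states:
            if s == NONWEAR_STATE:
                continue
            key = (
                "sedentary"
                if s in (STILL, FIDGET)
                else STATE_NAMES[s]
            )
            tallies[key] += factor
        return tallies


def _draw_clock(rng, mean, sd, lo, hi) -> int:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return int(round(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)))


def _draw_dwell_minutes(rng, median, sigma, lo, hi) -> float:
    return float(np.clip(rng.lognormal(np.log(median), sigma), lo, hi))


def _place_removals(rng, config, wake, bed, n_removals):
    """Sample non-overlapping removal windows inside [wake, bed) with a wear
    gap around each; resample on conflict, error after bounded retries."""
    if n_removals == 0:
        return []
    gap = config.removal_gap_min
    for _ in range(config.max_schedule_retries):
        durations = [
            int(
                round(
                    _draw_dwell_minutes(
                        rng,
                        config.removal_median_min,
                        config.removal_sigma,
                        config.removal_min_min,
                        config.removal_max_min,
                    )
                )
            )
            for _ in range(n_removals)
        ]
        lo, hi = wake + gap, bed - gap
        if hi - lo < sum(durations) + gap * (n_removals - 1):
            continue
        starts = sorted(int(rng.integers(lo, hi)) for _ in range(n_removals))
        periods = []
        ok = True
        prev_end = wake
        for start, dur in zip(starts, durations):
            if start < prev_end + gap or start + dur > bed - gap:
                ok = False
                break
            periods.append((start, start + dur))
            prev_end = start + dur
        if ok:
            return periods
    raise SimulationError(
        f"could not place {n_removals} removals in [{wake}, {bed}) after "
        f"{config.max_schedule_retries} retries"
    )


def _simulate_states(rng, config, n_epochs: int) -> np.ndarray:
    """Semi-Markov state path over a block of epochs."""
    per_min = 60 // config.epoch_seconds
    states = np.empty(n_epochs, dtype=np.int8)
    transitions = np.asarray(config.transitions)
    state = int(rng.choice(5, p=np.asarray(config.initial_probs)))
    pos = 0
    while pos < n_epochs:
        dwell_min = _draw_dwell_minutes(rng, *config.state_dwell(state))
        dwell_epochs = max(1, int(round(dwell_min * per_min)))
        states[pos : pos + dwell_epochs] = state
        pos += dwell_epochs
        state = int(rng.choice(5, p=transitions[state]))
    return states


def _emit_counts(rng, states: np.ndarray) -> np.ndarray:
    counts = np.zeros(len(states), dtype=np.int64)
    for state, (lo, hi) in STATE_COUNT_RANGES.items():
        mask = states == state
        if mask.any() and hi > 0:
            counts[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return counts


def _inject_spikes(rng, config, counts, wear_minute_mask) -> None:
    """Place 1-2-min handling artifacts inside true non-wear runs.

    Spikes sit at least 30 min from the run boundaries and from each other
    (brief handling in the middle of a long removal), and their counts stay
    below 100 cpm — the configuration under which the Troiano and Choi
    allowances absorb them while plain zero-window rules are split.
    """
    per_min = 60 // config.epoch_seconds
    margin = 30
    for iv in mask_to_intervals(~wear_minute_mask, NONWEAR):
        hours = iv.length / 60.0
        n_spikes = rng.poisson(config.nonwear_spike_rate * hours)
        placed: list[tuple[int, int]] = []
        for _ in range(n_spikes):
            dur = int(rng.integers(1, 3))  # 1 or 2 minutes
            lo, hi = iv.start_epoch + margin, iv.end_epoch - margin - dur
            if hi <= lo:
                continue
            start_min = int(rng.integers(lo, hi))
            if any(start_min < e + margin and s - margin < start_min + dur for s, e in placed):
                continue
            placed.append((start_min, start_min + dur))
            e0, e1 = start_min * per_min, (start_min + dur) * per_min
            counts[e0:e1] = rng.integers(1, config.spike_epoch_count_max + 1, size=e1 - e0)


def _perturb_diary(rng, config, wake, bed, periods):
    def jitter(t):
        return int(round(t + rng.normal(0, config.diary_noise_sd)))

    for _ in range(50):
        w, b = jitter(wake), jitter(bed)
        w = int(np.clip(w, 0, MINUTES_PER_DAY - 1))
        b = int(np.clip(b, w + 1, MINUTES_PER_DAY))
        offs = []
        ok = True
        prev = w
        for off, on in periods:
            o1, o2 = jitter(off), jitter(on)
            if not (prev <= o1 < o2 <= b):
                ok = False
                break
            offs.append((o1, o2))
            prev = o2
        if ok:
            return w, b, offs
    return wake, bed, list(periods)


def simulate_subject_day(
    config: SimulationConfig, subject_id: str, day_index: int, rng=None
) -> tuple[EpochSeries, DiaryRecord, GroundTruth]:
    """Generate one subject-day: counts, diary entry, and ground truth.

    Fully determined by ``(config.seed, subject_id, day_index)`` when ``rng``
    is not supplied.
    """
    if rng is None:
        subject_key = zlib.crc32(str(subject_id).encode()) % (2**31)
        rng = np.random.default_rng([config.seed, subject_key, day_index])
    per_min = 60 // config.epoch_seconds
    n_epochs = MINUTES_PER_DAY * per_min

    wake = _draw_clock(rng, config.wake_mean, config.wake_sd, config.wake_min, config.wake_max)
    bed = _draw_clock(rng, config.bed_mean, config.bed_sd, config.bed_min, config.bed_max)
    n_removals = int(rng.choice(len(config.removal_probs), p=np.asarray(config.removal_probs)))
    periods = _place_removals(rng, config, wake, bed, n_removals)

    wear_minute = np.zeros(MINUTES_PER_DAY, dtype=bool)
    wear_minute[wake:bed] = True
    for off, on in periods:
        wear_minute[off:on] = False

    states = np.full(n_epochs, NONWEAR_STATE, dtype=np.int8)
    day_states = _simulate_states(rng, config, (bed - wake) * per_min)
    states[wake * per_min : bed * per_min] = day_states
    wear_epoch = np.repeat(wear_minute, per_min)
    states[~wear_epoch] = NONWEAR_STATE

    counts = np.zeros(n_epochs, dtype=np.int64)
    counts[wear_epoch] = _emit_counts(rng, states[wear_epoch])
    if config.nonwear_spike_rate > 0:
        _inject_spikes(rng, config, counts, wear_minute)

    counts_ap = counts_ml = None
    if config.triaxial:
        # secondary axes co-active with the vertical axis, zero when it is zero
        active = counts > 0
        counts_ap = np.zeros_like(counts)
        counts_ml = np.zeros_like(counts)
        n_active = int(active.sum())
        if n_active:
            counts_ap[active] = np.maximum(
                1, np.rint(counts[active] * rng.uniform(0.5, 1.1, n_active))
            ).astype(np.int64)
            counts_ml[active] = np.maximum(
                1, np.rint(counts[active] * rng.uniform(0.3, 0.9, n_active))
            ).astype(np.int64)

    series = EpochSeries(
        subject_id=subject_id,
        day_index=day_index,
        start_clock=0,
        epoch_seconds=config.epoch_seconds,
        counts_vertical=counts,
        counts_ap=counts_ap,
        counts_ml=counts_ml,
    )

    d_wake, d_bed, d_offs = _perturb_diary(rng, config, wake, bed, periods)
    diary = DiaryRecord(
        subject_id=subject_id,
        day_index=day_index,
        wake_time=d_wake,
        bed_time=d_bed,
        off_periods=d_offs,
    )

    truth_intervals = mask_to_intervals(wear_minute, WEAR, "truth") + mask_to_intervals(
        ~wear_minute, NONWEAR, "truth"
    )
    truth = GroundTruth(
        subject_id=subject_id,
        day_index=day_index,
        wear_intervals=sorted(truth_intervals, key=lambda iv: iv.start_epoch),
        states=states,
        removal_count=len(periods),
    )
    return series, diary, truth


@dataclass
class CohortBundle:
    config: SimulationConfig
    series: list[EpochSeries]
    diaries: list[DiaryRecord]
    truths: list[GroundTruth]

    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.series:
            if s.subject_id not in seen:
                seen.append(s.subject_id)
        return seen


def simulate_cohort(config: SimulationConfig, out_dir: str | Path | None = None) -> CohortBundle:
    """Generate the full cohort; optionally write epoch, diary, and
    ground-truth files plus a manifest to ``out_dir``."""
    series, diaries, truths = [], [], []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:03d}"
        for day in range(1, config.days_per_subject + 1):
            rng = np.random.default_rng([config.seed, i, day])
            s, d, t = simulate_subject_day(config, subject_id, day, rng=rng)
            series.append(s)
            diaries.append(d)
            truths.append(t)
    bundle = CohortBundle(config=config, series=series, diaries=diaries, truths=truths)
    if out_dir is not None:
        write_cohort(bundle, out_dir)
    return bundle


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    awio.write_epoch_file(out / "epochs.csv", bundle.series)
    awio.write_diary_file(out / "diary.csv", bundle.diaries)
    records = [
        (t.subject_id, t.day_index, iv) for t in bundle.truths for iv in t.wear_intervals
    ]
    awio.intervals_to_frame(records, 60).to_csv(out / "truth_intervals.csv", index=False)
    manifest = {
        "config": _jsonable(asdict(bundle.config)),
        "n_subject_days": len(bundle.series),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a config from a plain mapping (YAML-friendly); a ``regime`` key
    of ``easy``/``hard`` selects the corresponding preset before overrides."""
    data = dict(data)
    regime = data.pop("regime", None)
    if "transitions" in data:
        data["transitions"] = tuple(tuple(row) for row in data["transitions"])
    if "dwell_params" in data:
        data["dwell_params"] = {int(k): tuple(v) for k, v in data["dwell_params"].items()}
    for key in ("removal_probs", "initial_probs"):
        if key in data:
            data[key] = tuple(data[key])
    if regime == "easy":
        return SimulationConfig.easy_regime(**data)
    if regime == "hard":
        return SimulationConfig.hard_regime(**data)
    if regime not in (None, "default"):
        raise ValueError(f"unknown regime {regime!r}")
    return SimulationConfig(**data)
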