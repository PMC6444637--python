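"""Delimited-text I/O for epoch files, diaries, intervals, and day summaries.

Epoch file format (comma-delimited by default)::

    # epoch_seconds=15
    subject_id,day,epoch_start_s,axis1,axis2,axis3

``epoch_start_s`` is seconds since midnight; ``axis2``/``axis3`` are optional.
The diary file mirrors a preprinted log sheet: one row per subject-day with
``HH:MM`` clock strings and up to five off/on slot pairs, unused slots empty.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DaySummary,
    DiaryRecord,
    EpochSeries,
    ParseError,
    WearInterval,
)

MAX_OFF_SLOTS = 5
_CLOCK_RE = re.compile(r"^(\d{1,2}):(\d{2})$")


def parse_clock(text: str) -> int:
    """``HH:MM`` → minutes past midnight.  Sub-minute input is rejected."""
    m = _CLOCK_RE.match(str(text).strip())
    if not m:
        raise ParseError(f"invalid clock time {text!r}; expected HH:MM")
    hours, minutes = int(m.group(1)), int(m.group(2))
    if hours > 24 or minutes > 59 or hours * 60 + minutes > 1440:
        raise ParseError(f"clock time {text!r} outside the day")
    return hours * 60 + minutes


def format_clock(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def _read_epoch_header(path: Path) -> int | None:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"epoch_seconds\s*=\s*(\d+)", line)
                if m:
                    return int(m.group(1))
                continue
            break
    return None


def read_epoch_file(
    path: str | Path, epoch_seconds: int | None = None, delimiter: str = ","
) -> list[EpochSeries]:
    """Read a delimited epoch file into one :class:`EpochSeries` per subject-day.

    The epoch length comes from a ``# epoch_seconds=N`` header line or the
    ``epoch_seconds`` argument (argument wins).  Rows are validated: counts
    must be non-negative and timestamps strictly increasing with a uniform
    stride of one epoch; violations raise :class:`ParseError` naming the row.
    """
    path = Path(path)
    header_epoch = _read_epoch_header(path)
    epoch_seconds = epoch_seconds or header_epoch
    if epoch_seconds is None:
        raise ParseError(f"{path}: epoch length not declared in header or argument")
    if header_epoch is not None and epoch_seconds != header_epoch:
        raise ParseError(
            f"{path}: mixed epoch lengths (header {header_epoch}s, requested {epoch_seconds}s)"
        )
    df = pd.read_csv(path, sep=delimiter, comment="#")
    required = {"subject_id", "day", "epoch_start_s", "axis1"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    axes = ["axis1"] + [c for c in ("axis2", "axis3") if c in df.columns]
    for col in axes:
        bad = df.index[(df[col] < 0) | ~np.isfinite(df[col])]
        if len(bad):
            raise ParseError(f"{path}: negative or non-finite count at data row {bad[0] + 1}")
    out: list[EpochSeries] = []
    for (subject, day), grp in df.groupby(["subject_id", "day"], sort=True):
        starts = grp["epoch_start_s"].to_numpy()
        strides = np.diff(starts)
        if np.any(strides <= 0):
            row = grp.index[1:][strides <= 0][0] + 1
            raise ParseError(f"{path}: non-monotone timestamp at data row {row}")
        if np.any(strides != epoch_seconds):
            row = grp.index[1:][strides != epoch_seconds][0] + 1
            raise ParseError(
                f"{path}: timestamp stride != {epoch_seconds}s at data row {row}"
            )
        out.append(
            EpochSeries(
                subject_id=str(subject),
                day_index=int(day),
                start_clock=int(starts[0]) // 60,
                epoch_seconds=epoch_seconds,
                counts_vertical=grp["axis1"].to_numpy(),
                counts_ap=grp["axis2"].to_numpy() if "axis2" in axes else None,
                counts_ml=grp["axis3"].to_numpy() if "axis3" in axes else None,
            )
        )
    return out


def write_epoch_file(
    path: str | Path, series_list: list[EpochSeries], delimiter: str = ","
) -> None:
    if not series_list:
        raise ValueError("nothing to write")
    epoch_seconds = series_list[0].epoch_seconds
    if any(s.epoch_seconds != epoch_seconds for s in series_list):
        raise ValueError("mixed epoch lengths in one file")
    frames = []
    for s in series_list:
        starts = s.start_clock * 60 + np.arange(s.n_epochs) * epoch_seconds
        data = {
            "subject_id": s.subject_id,
            "day": s.day_index,
            "epoch_start_s": starts,
            "axis1": s.counts_vertical,
        }
        if s.counts_ap is not None:
            data["axis2"] = s.counts_ap
        if s.counts_ml is not None:
            data["axis3"] = s.counts_ml
        frames.append(pd.DataFrame(data))
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# epoch_seconds={epoch_seconds}\n")
        df.to_csv(fh, sep=delimiter, index=False)


def read_diary_file(path: str | Path, delimiter: str = ",") -> list[DiaryRecord]:
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str)
    required = {"subject_id", "day", "wake", "bed"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        offs: list[tuple[int, int]] = []
        for i in range(1, MAX_OFF_SLOTS + 1):
            a, b = row.get(f"off{i}_start"), row.get(f"off{i}_end")
            a_empty = pd.isna(a) or str(a).strip() == ""
            b_empty = pd.isna(b) or str(b).strip() == ""
            if a_empty and b_empty:
                continue
            if a_empty or b_empty:
                raise ParseError(f"{path}: half-filled off slot {i} for {row['subject_id']}")
            offs.append((parse_clock(a), parse_clock(b)))
        records.append(
            DiaryRecord(
                subject_id=str(row["subject_id"]),
                day_index=int(row["day"]),
                wake_time=parse_clock(row["wake"]),
                bed_time=parse_clock(row["bed"]),
                off_periods=offs,
            )
        )
    return records


def write_diary_file(path: str | Path, diaries: list[DiaryRecord], delimiter: str = ",") -> None:
    rows = []
    for d in diaries:
        row = {
            "subject_id": d.subject_id,
            "day": d.day_index,
            "wake": format_clock(d.wake_time),
            "bed": format_clock(d.bed_time),
        }
        for i in range(1, MAX_OFF_SLOTS + 1):
            off = d.off_periods[i - 1] if i <= len(d.off_periods) else None
            row[f"off{i}_start"] = format_clock(off[0]) if off else ""
            row[f"off{i}_end"] = format_clock(off[1]) if off else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def intervals_to_frame(
    records: list[tuple[str, int, WearInterval]], epoch_seconds: int
) -> pd.DataFrame:
    """Flatten (subject, day, interval) triples to a minute-based table."""
    factor = epoch_seconds / 60.0
    rows = [
        {
            "subject_id": subject,
            "day": day,
            "start_min": iv.start_epoch * factor,
            "end_min": iv.end_epoch * factor,
            "state": iv.state,
            "rule": iv.source,
        }
        for subject, day, iv in records
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "day", "start_min", "end_min", "state", "rule"]
    )


def frame_to_intervals(
    df: pd.DataFrame, epoch_seconds: int
) -> dict[tuple[str, int, str], list[WearInterval]]:
    """Inverse of :func:`intervals_to_frame`, keyed by (subject, day, rule)."""
    factor = 60.0 / epoch_seconds
    out: dict[tuple[str, int, str], list[WearInterval]] = {}
    for _, row in df.iterrows():
        start = row["start_min"] * factor
        end = row["end_min"] * factor
        if start != int(start) or end != int(end):
            raise ParseError("interval bounds do not align with the epoch grid")
        key = (str(row["subject_id"]), int(row["day"]), str(row["rule"]))
        out.setdefault(key, []).append(
            WearInterval(int(start), int(end), str(row["state"]), str(row["rule"]))
        )
    for ivs in out.values():
        ivs.sort(key=lambda iv: iv.start_epoch)
    return out


SUMMARY_COLUMNS = [
    "subject_id",
    "day",
    "rule",
    "wear_min",
    "sedentary_min",
    "light_min",
    "moderate_min",
    "vigorous_min",
    "mvpa_min",
    "nonwear_period_count",
]


def summaries_to_frame(summaries: list[DaySummary]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "day": s.day_index,
            "rule": s.rule,
            "wear_min": s.wear_min,
            "sedentary_min": s.sedentary_min,
            "light_min": s.light_min,
            "moderate_min": s.moderate_min,
            "vigorous_min": s.vigorous_min,
            "mvpa_min": s.mvpa_min,
            "nonwear_period_count": s.nonwear_period_count,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def frame_to_summaries(df: pd.DataFrame) -> list[DaySummary]:
    return [
        DaySummary(
            subject_id=str(r["subject_id"]),
            day_index=int(r["day"]),
            rule=str(r["rule"]),
            wear_min=float(r["wear_min"]),
            sedentary_min=float(r["sedentary_min"]),
            light_min=float(r["light_min"]),
            moderate_min=float(r["moderate_min"]),
            vigorous_min=float(r["vigorous_min"]),
            nonwear_period_count=int(r["nonwear_period_count"]),
        )
        for _, r in df.iterrows()
    ]
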