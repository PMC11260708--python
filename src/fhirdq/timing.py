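"""Query-response-time summarization.

Each case query has start and completion event timestamps; the end-to-end
duration (whole seconds) is summarized per window mode with min, max,
range, median, average and IQR, formatted H:MM:SS for reporting.  No
per-hop attribution is attempted — the measured interval spans the whole
exchange round trip by design.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cases import WindowMode


@dataclass(frozen=True)
class QueryTiming:
    case_id: str
    window_mode: WindowMode
    started_at: _dt.datetime
    completed_at: _dt.datetime

    def __post_init__(self) -> None:
        if self.completed_at < self.started_at:
            raise ValueError(f"case {self.case_id}: completed before started")

    @property
    def duration_s(self) -> int:
        return int((self.completed_at - self.started_at).total_seconds())


@dataclass(frozen=True)
class ModeTiming:
    """Duration statistics for one window mode, in seconds."""

    window_mode: WindowMode
    n: int
    min_s: int
    max_s: int
    range_s: int
    median_s: float
    average_s: float
    iqr_s: float

    def row_hms(self) -> dict[str, str]:
        return {
            "case_type": self.window_mode.value,
            "minimum": format_hms(self.min_s),
            "maximum": format_hms(self.max_s),
            "range": format_hms(self.range_s),
            "median": format_hms(int(round(self.median_s))),
        }


@dataclass
class TimingSummary:
    modes: dict[WindowMode, ModeTiming]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame([m.row_hms() for m in self.modes.values()])


def summarize_durations(timings: Iterable[QueryTiming]) -> TimingSummary:
    """Per-mode order statistics of query durations.

    Median of an even count is the mean of the central pair; the IQR uses
    linear interpolation between order statistics (quantile type 7).  Modes
    with no timings are omitted.
    """
    by_mode: dict[WindowMode, list[int]] = {}
    for t in timings:
        by_mode.setdefault(t.window_mode, []).append(t.duration_s)
    modes: dict[WindowMode, ModeTiming] = {}
    for mode in (WindowMode.LIMITED, WindowMode.ENTIRE_STUDY):
        durations = by_mode.get(mode)
        if not durations:
            continue
        arr = np.asarray(sorted(durations), dtype=float)
        q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
        modes[mode] = ModeTiming(
            window_mode=mode,
            n=len(arr),
            min_s=int(arr.min()),
            max_s=int(arr.max()),
            range_s=int(arr.max() - arr.min()),
            median_s=float(np.median(arr)),
            average_s=float(arr.mean()),
            iqr_s=float(q3 - q1),
        )
    return TimingSummary(modes)


def format_hms(seconds: int) -> str:
    """Format whole seconds as H:MM:SS (hours unpadded)."""
    if seconds < 0:
        raise ValueError("negative duration")
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h}:{m:02d}:{s:02d}"


def parse_hms(text: str) -> int:
    """Inverse of format_hms."""
    h, m, s = text.split(":")
    return int(h) * 3600 + int(m) * 60 + int(s)


TIMING_COLUMNS = ["case_id", "window_mode", "started_at", "completed_at"]


def read_timings(path: str | Path) -> list[QueryTiming]:
    """Read the timing file (CSV with ISO-8601 timestamps)."""
    out: list[QueryTiming] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(QueryTiming(
                case_id=row["case_id"],
                window_mode=WindowMode(row["window_mode"]),
                started_at=_dt.datetime.fromisoformat(row["started_at"]),
                completed_at=_dt.datetime.fromisoformat(row["completed_at"]),
            ))
    return out


def write_timings(timings: Sequence[QueryTiming], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TIMING_COLUMNS)
        for t in timings:
            writer.writerow([
                t.case_id, t.window_mode.value,
                t.started_at.isoformat(), t.completed_at.isoformat(),
            ])
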