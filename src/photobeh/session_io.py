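"""On-disk interchange and the core in-memory containers.

Everything crosses the disk boundary as comma-delimited text:

* recordings      — ``time_s,f465,f405``
* movement traces — ``time_s,movement_score``
* event schedules — ``onset_s,offset_s,event_type,day,condition,subject_id``
* results         — long-format tables written by :func:`write_results`

Time is seconds from session start, 0-based. Events use half-open
``[onset, offset)`` semantics so boundary samples are never double-counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("photobeh")

EVENT_TYPES = frozenset({"cs", "shock", "cs_offset_probe"})
CONDITIONS = frozenset({"safety", "threat", "control"})


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TwoChannelRecording:
    """Uniformly sampled 465 nm (calcium-dependent) and 405 nm (isosbestic
    control) fluorescence traces sharing one time base."""

    time_s: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        n = len(self.time_s)
        if not (len(self.f465) == len(self.f405) == n):
            raise ValueError("channel lengths differ from time base")
        if n >= 2:
            dt = np.median(np.diff(self.time_s))
            if abs(dt - 1.0 / self.sampling_rate_hz) > 1e-6:
                raise ValueError(
                    f"time base step {dt:.6g}s inconsistent with "
                    f"sampling_rate_hz={self.sampling_rate_hz}")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class MovementTrace:
    """ANY-maze-style movement score over time (arbitrary units; larger
    values mean more movement)."""

    time_s: np.ndarray
    score: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        if len(self.time_s) != len(self.score):
            raise ValueError("score length differs from time base")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class Event:
    onset_s: float
    offset_s: float
    event_type: str
    day: str = "day1"
    condition: str = "control"
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        if self.onset_s > self.offset_s:
            raise ValueError(f"event onset {self.onset_s} > offset {self.offset_s}")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"event_type {self.event_type!r} not in {sorted(EVENT_TYPES)}")


@dataclass
class EventSchedule:
    """Timestamped, typed events sorted by onset."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)

    def of_type(self, event_type: str) -> "EventSchedule":
        return EventSchedule([e for e in self.events if e.event_type == event_type])

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REC_COLUMNS = ("time_s", "f465", "f405")


def _load_table(path: str | Path, required: Sequence[str],
                column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n_before = len(df)
    df = df.dropna(subset=list(required)).reset_index(drop=True)
    dropped = n_before - len(df)
    if dropped:
        level = logging.WARNING if dropped > 0.01 * n_before else logging.INFO
        log.log(level, "%s: dropped %d/%d rows with missing fields",
                path.name, dropped, n_before)
    return df


def _bin_mean_resample(time_s: np.ndarray, columns: list[np.ndarray],
                       rate_hz: float) -> tuple[np.ndarray, list[np.ndarray]]:
    """Resample onto a uniform grid at ``rate_hz`` by averaging all raw
    samples falling in each 1/rate bin (bin k covers [k, k+1)/rate).

    Bins left empty by dropped rows are filled by linear interpolation so
    the output grid has no missing samples."""
    bins = np.floor(time_s * rate_hz).astype(np.int64)
    bins -= bins.min()
    n_bins = bins.max() + 1
    counts = np.bincount(bins, minlength=n_bins)
    filled = counts > 0
    grid = np.arange(n_bins)
    out_cols = []
    for col in columns:
        sums = np.bincount(bins, weights=col, minlength=n_bins)
        means = sums[filled] / counts[filled]
        out_cols.append(np.interp(grid, grid[filled], means))
    new_time = grid / rate_hz + time_s.min()
    return new_time, out_cols


def read_recording(path: str | Path,
                   column_map: Mapping[str, str] | None = None,
                   target_rate_hz: float | None = None) -> TwoChannelRecording:
    """Read a two-channel recording from delimited text.

    ``column_map`` maps raw header names onto ``time_s``/``f465``/``f405``.
    If the raw time base is irregular or faster than ``target_rate_hz``, the
    trace is resampled by binning-mean onto that rate.
    """
    df = _load_table(path, _REC_COLUMNS, column_map)
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 usable samples")
    t = df["time_s"].to_numpy(float)
    f465 = df["f465"].to_numpy(float)
    f405 = df["f405"].to_numpy(float)
    order = np.argsort(t, kind="stable")
    t, f465, f405 = t[order], f465[order], f405[order]

    dts = np.diff(t)
    native_rate = 1.0 / np.median(dts)
    irregular = np.ptp(dts) > 1e-6
    if target_rate_hz is not None and (irregular
                                       or native_rate > target_rate_hz * (1 + 1e-6)):
        t, (f465, f405) = _bin_mean_resample(t, [f465, f405], target_rate_hz)
        rate = target_rate_hz
        log.info("%s: resampled %.4g Hz -> %.4g Hz (%d samples)",
                 Path(path).name, native_rate, rate, len(t))
    else:
        rate = native_rate
    return TwoChannelRecording(t, f465, f405, sampling_rate_hz=rate)


def write_recording(rec: TwoChannelRecording, path: str | Path) -> None:
    pd.DataFrame({"time_s": rec.time_s, "f465": rec.f465,
                  "f405": rec.f405}).to_csv(path, index=False)


def read_movement(path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> MovementTrace:
    df = _load_table(path, ("time_s", "movement_score"), column_map)
    if len(df) < 2:
        raise ValueError(f"{path}: fewer than 2 usable samples")
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / np.median(np.diff(t))
    return MovementTrace(t, df["movement_score"].to_numpy(float),
                         sampling_rate_hz=rate)


def write_movement(trace: MovementTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s,
                  "movement_score": trace.score}).to_csv(path, index=False)


_SCHED_COLUMNS = ("onset_s", "offset_s", "event_type", "day", "condition",
                  "subject_id")


def read_schedule(path: str | Path) -> EventSchedule:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        return EventSchedule([])
    for col in _SCHED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    events = []
    for i, row in df.iterrows():
        try:
            events.append(Event(float(row.onset_s), float(row.offset_s),
                                str(row.event_type), str(row.day),
                                str(row.condition), str(row.subject_id)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row {i + 2}: {exc}") from exc
    return EventSchedule(events)


def write_schedule(schedule: EventSchedule, path: str | Path) -> None:
    pd.DataFrame(
        [(e.onset_s, e.offset_s, e.event_type, e.day, e.condition, e.subject_id)
         for e in schedule.events],
        columns=_SCHED_COLUMNS).to_csv(path, index=False)


def write_results(tables: Mapping[str, pd.DataFrame],
                  out_dir: str | Path) -> dict[str, Path]:
    """Write each named table as ``<name>.csv`` under ``out_dir``.

    The output directory is validated (created and probed for writability)
    before anything is written, so a bad destination fails fast.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable") from exc
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
        log.info("wrote %s (%d rows)", p, len(df))
    return paths
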