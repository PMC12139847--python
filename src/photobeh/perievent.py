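"""Event-locked epoching, pre-event baseline normalization, two-stage
averaging and trapezoidal AUC.

Epochs are cut on the recording's own sampling grid: the sample at relative
time 0 is the first sample at-or-after the event onset (half-open
convention), and every trial of a tensor shares one relative-time grid from
``-pre_s`` to ``+post_s``. The pre-event mean (the preCS period for CS
trials) is subtracted from each trial before averaging. Averaging is
two-stage — trials to a subject mean, then an unweighted mean across
subjects — so subjects with more trials are not overweighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .session_io import EventSchedule
from .signals import ZTrace


@dataclass
class PeriEventTensor:
    """Per-trial event-locked waveforms for one subject.

    ``values`` has shape (n_trials, n_time); ``rel_time_s`` is seconds
    relative to event onset.
    """

    rel_time_s: np.ndarray
    values: np.ndarray
    event_type: str
    window: tuple[float, float]          # (pre_s, post_s)
    baseline: tuple[float, float] | None  # [start_s, end_s) rel. to onset
    subject_id: str = "s0"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.rel_time_s = np.asarray(self.rel_time_s, float)
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != len(self.rel_time_s):
            raise ValueError("trial length differs from relative time grid")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AucResult:
    subject_id: str
    interval_name: str
    start_s: float
    end_s: float
    auc: float  # z * s


def extract_epochs(z: ZTrace, schedule: EventSchedule, event_type: str,
                   window: tuple[float, float],
                   subject_id: str | None = None) -> PeriEventTensor:
    """Cut one window per event of ``event_type`` around its onset.

    Events whose window is not fully inside the recording are dropped and
    counted in ``n_dropped``; zero retained trials is an error.
    """
    pre_s, post_s = window
    rate = z.sampling_rate_hz
    pre_n = int(round(pre_s * rate))
    post_n = int(round(post_s * rate))
    rel_time = np.arange(-pre_n, post_n + 1) / rate
    t0 = z.time_s[0]

    rows, dropped = [], 0
    events = [e for e in schedule if e.event_type == event_type]
    for ev in events:
        # first sample at-or-after onset (half-open convention)
        idx = math.ceil((ev.onset_s - t0) * rate - 1e-9)
        lo, hi = idx - pre_n, idx + post_n
        if lo < 0 or hi >= len(z.z):
            dropped += 1
            continue
        rows.append(z.z[lo:hi + 1])
    if not rows:
        raise ValueError(
            f"no {event_type!r} trial fits inside the recording "
            f"({len(events)} scheduled, {dropped} dropped)")
    if subject_id is None:
        subject_id = events[0].subject_id
    return PeriEventTensor(rel_time, np.vstack(rows), event_type,
                           (pre_s, post_s), baseline=None,
                           subject_id=subject_id, n_dropped=dropped)


def baseline_normalize(tensor: PeriEventTensor,
                       baseline: tuple[float, float]) -> PeriEventTensor:
    """Subtract each trial's mean over ``baseline`` = [start_s, end_s)
    (relative to onset) from the whole trial. Idempotent."""
    start, end = baseline
    mask = (tensor.rel_time_s >= start - 1e-9) & (tensor.rel_time_s < end - 1e-9)
    if not mask.any():
        raise ValueError(f"baseline window [{start}, {end}) contains no samples")
    means = tensor.values[:, mask].mean(axis=1, keepdims=True)
    return replace(tensor, values=tensor.values - means, baseline=(start, end))


def subject_mean(tensor: PeriEventTensor) -> np.ndarray:
    """Mean waveform over a subject's trials."""
    return tensor.values.mean(axis=0)


def group_mean(per_subject_waveforms: np.ndarray) -> np.ndarray:
    """Unweighted mean across subjects of per-subject mean waveforms
    (shape (n_subjects, n_time))."""
    w = np.atleast_2d(np.asarray(per_subject_waveforms, float))
    return w.mean(axis=0)


def stack_subject_means(tensors: list[PeriEventTensor]) -> np.ndarray:
    """Per-subject mean waveforms stacked to (n_subjects, n_time)."""
    grids = {t.values.shape[1] for t in tensors}
    if len(grids) != 1:
        raise ValueError("tensors do not share a time grid")
    return np.vstack([subject_mean(t) for t in tensors])


def auc(rel_time_s: np.ndarray, waveform: np.ndarray,
        interval: tuple[float, float], *, interval_name: str = "",
        subject_id: str = "") -> AucResult:
    """Composite-trapezoid area of ``waveform`` over ``interval`` seconds.

    Interval endpoints falling between grid samples are linearly
    interpolated so the area is exact for piecewise-linear waveforms and
    additive over contiguous splits.
    """
    start, end = interval
    if start >= end:
        raise ValueError(f"empty or inverted interval [{start}, {end}]")
    rel_time_s = np.asarray(rel_time_s, float)
    if start < rel_time_s[0] - 1e-9 or end > rel_time_s[-1] + 1e-9:
        raise ValueError(
            f"interval [{start}, {end}] outside waveform range "
            f"[{rel_time_s[0]}, {rel_time_s[-1]}]")
    inner = (rel_time_s > start) & (rel_time_s < end)
    knots = np.concatenate(([start], rel_time_s[inner], [end]))
    vals = np.interp(knots, rel_time_s, waveform)
    area = float(np.trapezoid(vals, knots))
    return AucResult(subject_id, interval_name, start, end, area)
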