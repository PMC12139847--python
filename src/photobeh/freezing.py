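"""Freezing detection from movement scores, with hysteresis thresholds.

A freezing bout begins when the movement score drops below the onset
threshold (60) and stays there continuously for at least the minimum
duration (2 s); once confirmed, the bout is scored from the first
sub-threshold sample and persists until the score rises above the offset
threshold (70). The 60-70 hysteresis band means brief wobbles between the
two thresholds do not fragment a bout. Boundary-equal samples continue the
current state ("below"/"rose above" are strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session_io import MovementTrace


@dataclass(frozen=True)
class FreezingBout:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FreezingSummary:
    subject_id: str
    epoch_name: str
    percent_freezing: float
    cs_minus_precs: float | None = None  # percentage points


def detect_freezing(trace: MovementTrace, onset_thr: float = 60.0,
                    offset_thr: float = 70.0,
                    min_dur_s: float = 2.0) -> list[FreezingBout]:
    """Hysteresis bout detection on a uniform movement-score trace.

    Candidate onset at the first sample with score < ``onset_thr``; the
    candidate is cancelled by any sample >= ``onset_thr`` before the
    sub-threshold condition has lasted ``min_dur_s`` continuously. A
    confirmed bout starts retroactively at the candidate onset and ends at
    the first sample with score > ``offset_thr`` (or at the end of the
    trace).
    """
    if onset_thr >= offset_thr:
        raise ValueError(f"onset_thr ({onset_thr}) must be < offset_thr "
                         f"({offset_thr})")
    score = trace.score
    t = trace.time_s
    n = len(score)
    if n == 0:
        return []
    dt = 1.0 / trace.sampling_rate_hz

    bouts: list[FreezingBout] = []
    state = "moving"
    cand_start_i = 0
    for i in range(n):
        s = score[i]
        if state == "moving":
            if s < onset_thr:
                state = "candidate"
                cand_start_i = i
        elif state == "candidate":
            if s < onset_thr:
                # duration covered by samples cand_start_i..i inclusive
                if (i - cand_start_i + 1) * dt >= min_dur_s - 1e-9:
                    state = "frozen"
            else:
                state = "moving"
        elif state == "frozen":
            if s > offset_thr:
                bouts.append(FreezingBout(float(t[cand_start_i]), float(t[i])))
                state = "candidate" if s < onset_thr else "moving"
    if state == "frozen":
        bouts.append(FreezingBout(float(t[cand_start_i]), float(t[-1] + dt)))

    # merge gaps shorter than one sample period
    merged: list[FreezingBout] = []
    for b in bouts:
        if merged and b.start_s - merged[-1].end_s < dt - 1e-9:
            merged[-1] = FreezingBout(merged[-1].start_s, b.end_s)
        else:
            merged.append(b)
    return merged


def percent_freezing(bouts: list[FreezingBout],
                     epoch: tuple[float, float]) -> float:
    """Percent of the epoch spent inside freezing bouts (bouts clipped to
    the epoch boundaries)."""
    start, end = epoch
    if end <= start:
        raise ValueError(f"empty epoch [{start}, {end}]")
    covered = sum(max(0.0, min(b.end_s, end) - max(b.start_s, start))
                  for b in bouts)
    return 100.0 * covered / (end - start)


def contrast_cs_precs(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject CS-minus-preCS freezing contrast.

    ``trial_table`` has one row per trial with columns ``subject_id``,
    ``trial``, ``precs_percent``, ``cs_percent``. Per-trial differences are
    averaged within subject; the returned frame has one row per subject
    with columns ``subject_id``, ``precs_percent``, ``cs_percent``,
    ``cs_minus_precs`` (group-level averaging across subjects is then a
    plain unweighted mean of that column).
    """
    required = {"subject_id", "precs_percent", "cs_percent"}
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    df = trial_table.copy()
    df["cs_minus_precs"] = df["cs_percent"] - df["precs_percent"]
    out = (df.groupby("subject_id", sort=True)
             [["precs_percent", "cs_percent", "cs_minus_precs"]]
             .mean().reset_index())
    return out


def shift_movement_for_plot(trace: MovementTrace,
                            onset_thr: float = 60.0) -> MovementTrace:
    """Presentation-only shift: subtract the freezing onset threshold so
    values below zero mark freezing time points. Never used for detection."""
    return MovementTrace(trace.time_s, trace.score - onset_thr,
                         trace.sampling_rate_hz)
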