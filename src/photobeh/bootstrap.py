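"""Bootstrapped confidence-interval waveform analysis.

The unit of resampling is the subject-level mean waveform: whole waveforms
are drawn with replacement across subjects (preserving the time
autocorrelation of each waveform), the group mean is recomputed per draw,
and pointwise percentile limits of the bootstrap-mean distribution form the
confidence band. Each half-width about the bootstrap-distribution mean is
then expanded by n/(n-1) to counter the narrowness bias of percentile
intervals at small n.

A *significant transient* is a maximal run of samples where the band
excludes zero, the group mean additionally exceeds the +/-0.5 z threshold,
and the run lasts at least 1/3 s. Between-condition comparisons bootstrap
the difference waveform (within-subject differences when paired,
independent group resampling when not) and apply the same run rule without
the magnitude threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class BootstrapSettings:
    n_boot: int = 1000
    alpha: float = 0.05
    threshold: float = 0.5       # z units; vs-zero test only
    min_run_s: float = 1.0 / 3.0
    expand: bool = True          # n/(n-1) half-width expansion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.min_run_s <= 0:
            raise ValueError("min_run_s must be > 0")


@dataclass
class WaveformSummary:
    """Group mean waveform with pointwise bootstrap confidence band."""

    rel_time_s: np.ndarray
    mean: np.ndarray        # point estimate: mean of subject waveforms
    boot_mean: np.ndarray   # mean of the bootstrap distribution
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_subjects: int

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.rel_time_s)))


@dataclass
class SignificanceMask:
    """Non-overlapping significant runs, each (start_s, end_s, sign)."""

    runs: list[tuple[float, float, str]] = field(default_factory=list)
    min_run_s: float = 1.0 / 3.0

    def total_duration_s(self) -> float:
        return sum(end - start for start, end, _ in self.runs)

    def __len__(self) -> int:
        return len(self.runs)


def _percentile_band(boots: np.ndarray, alpha: float, n: int, expand: bool,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile limits of bootstrap means, half-widths expanded about the
    bootstrap-distribution mean by n/(n-1)."""
    lo = np.percentile(boots, 100.0 * alpha / 2.0, axis=0)
    hi = np.percentile(boots, 100.0 * (1.0 - alpha / 2.0), axis=0)
    bm = boots.mean(axis=0)
    if expand and n > 1:
        factor = n / (n - 1.0)
        lo = bm - factor * (bm - lo)
        hi = bm + factor * (hi - bm)
    return bm, lo, hi


def bootstrap_ci(per_subject_waveforms: np.ndarray, rel_time_s: np.ndarray,
                 settings: BootstrapSettings,
                 rng: np.random.Generator | None = None) -> WaveformSummary:
    """Confidence band on the group mean by resampling subjects.

    ``per_subject_waveforms`` has shape (n_subjects, n_time); whole
    waveforms are resampled jointly. Deterministic given ``settings.seed``
    (or an explicit ``rng``).
    """
    w = np.atleast_2d(np.asarray(per_subject_waveforms, float))
    n = w.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 subjects for a confidence band, got {n}")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    idx = rng.integers(0, n, size=(settings.n_boot, n))
    boots = w[idx].mean(axis=1)  # (n_boot, n_time)
    bm, lo, hi = _percentile_band(boots, settings.alpha, n, settings.expand)
    return WaveformSummary(np.asarray(rel_time_s, float), w.mean(axis=0),
                           bm, lo, hi, n_subjects=n)


def _runs_from_candidates(candidates: np.ndarray, sign: np.ndarray,
                          rel_time_s: np.ndarray, rate_hz: float,
                          min_run_s: float) -> list[tuple[float, float, str]]:
    """Maximal same-sign candidate runs of at least ceil(min_run_s * rate)
    samples; a run of k samples spans k/rate seconds."""
    min_samples = max(1, math.ceil(min_run_s * rate_hz - 1e-9))
    runs: list[tuple[float, float, str]] = []
    i, n = 0, len(candidates)
    dt = 1.0 / rate_hz
    while i < n:
        if not candidates[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and candidates[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        if j - i + 1 >= min_samples:
            runs.append((float(rel_time_s[i]), float(rel_time_s[j] + dt),
                         "+" if sign[i] > 0 else "-"))
        i = j + 1
    return runs


def significant_runs(summary: WaveformSummary, settings: BootstrapSettings,
                     ) -> SignificanceMask:
    """Detect significant transients against zero.

    A sample is a positive candidate when the lower band limit is above 0
    AND the mean exceeds ``threshold``; a negative candidate symmetrically.
    Maximal same-sign candidate runs lasting at least ``min_run_s`` are
    reported. An empty mask is a valid outcome.
    """
    pos = (summary.ci_lo > 0) & (summary.mean > settings.threshold)
    neg = (summary.ci_hi < 0) & (summary.mean < -settings.threshold)
    candidates = pos | neg
    sign = np.where(pos, 1, -1)
    runs = _runs_from_candidates(candidates, sign, summary.rel_time_s,
                                 summary.sampling_rate_hz, settings.min_run_s)
    return SignificanceMask(runs, settings.min_run_s)


def compare_waveforms(group_a: np.ndarray, group_b: np.ndarray,
                      rel_time_s: np.ndarray, settings: BootstrapSettings,
                      paired: bool = False,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[WaveformSummary, SignificanceMask]:
    """Between-condition comparison: runs where the bootstrap band of the
    A-minus-B difference excludes zero for at least ``min_run_s``.

    Paired mode bootstraps the mean of within-subject difference waveforms
    (rows of the two groups must be the same subjects in the same order);
    unpaired mode resamples each group independently and uses
    n = min(nA, nB) for the narrowness expansion. No magnitude threshold is
    applied to differences.
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups do not share a time grid")
    if rng is None:
        rng = np.random.default_rng(settings.seed)

    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError(
                f"paired comparison needs matched subjects; got {a.shape[0]} "
                f"vs {b.shape[0]}")
        summary = bootstrap_ci(a - b, rel_time_s, settings, rng=rng)
    else:
        na, nb = a.shape[0], b.shape[0]
        if na < 2 or nb < 2:
            raise ValueError("need >= 2 subjects per group")
        idx_a = rng.integers(0, na, size=(settings.n_boot, na))
        idx_b = rng.integers(0, nb, size=(settings.n_boot, nb))
        boots = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
        bm, lo, hi = _percentile_band(boots, settings.alpha, min(na, nb),
                                      settings.expand)
        summary = WaveformSummary(np.asarray(rel_time_s, float),
                                  a.mean(axis=0) - b.mean(axis=0),
                                  bm, lo, hi, n_subjects=min(na, nb))

    pos = summary.ci_lo > 0
    neg = summary.ci_hi < 0
    sign = np.where(pos, 1, -1)
    runs = _runs_from_candidates(pos | neg, sign, summary.rel_time_s,
                                 summary.sampling_rate_hz, settings.min_run_s)
    return summary, SignificanceMask(runs, settings.min_run_s)
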