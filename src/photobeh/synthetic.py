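"""Synthetic conditioning sessions with known ground truth.

Emulates a Doric-style two-channel fiber-photometry recording of a
conditioning session: a calcium-dependent 465 nm channel carrying
GCaMP6f-like transients locked to scheduled events, and a 405 nm isosbestic
channel sharing the bleaching and motion artifacts but blind to calcium.
Movement-score traces with embedded freezing bouts emulate the video-tracking
output scored alongside the photometry.

Every injected transient and freezing bout is recorded in a
:class:`GroundTruth` sidecar so downstream stages can be tested against
exactly known inputs.

Randomness: one seeded generator per session; draws happen in a fixed order
(inter-trial intervals, then per-event amplitudes, then motion, then the
465 noise, then the 405 noise) so a seed pins the session byte-for-byte
across versions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session_io import Event, EventSchedule, MovementTrace, TwoChannelRecording


class ScheduleError(ValueError):
    """The requested events cannot be placed inside the session."""


@dataclass
class SessionConfig:
    """Timing layout of one conditioning session.

    Defaults follow the conditioning design this package targets: 20 s tone
    CSs and 2 s foot shocks separated by pseudo-random 70-120 s intervals
    after a 2-minute habituation period.
    """

    duration_s: float
    n_cs: int = 4
    n_shock: int = 0
    sampling_rate_hz: float = 30.0
    cs_duration_s: float = 20.0
    shock_duration_s: float = 2.0
    iti_range_s: tuple[float, float] = (70.0, 120.0)
    habituation_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        lo, hi = self.iti_range_s
        if lo > hi:
            raise ValueError(f"iti_range_s min {lo} > max {hi}")
        if self.n_cs < 0 or self.n_shock < 0:
            raise ValueError("event counts must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class TransientModel:
    """Double-exponential calcium transient kernel, peak-normalized.

    ``rise_tau_s``/``decay_tau_s`` default to fast-GCaMP-like kinetics
    (0.1 s rise, 0.8 s decay); the amplitude is the true peak dF/F of each
    evoked response, jittered per event and truncated at zero (responses are
    modeled as non-negative).
    """

    rise_tau_s: float = 0.1
    decay_tau_s: float = 0.8
    amplitude: float = 0.05
    amplitude_jitter_sd: float = 0.0
    latency_s: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("kernel time constants must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def peak_time_s(self) -> float:
        """Time of the kernel maximum after event onset (plus latency)."""
        return (self.rise_tau_s
                * math.log1p(self.decay_tau_s / self.rise_tau_s)
                + self.latency_s)

    def kernel(self, rel_time_s: np.ndarray) -> np.ndarray:
        """Unit-peak kernel (1 - e^(-t/rise)) * e^(-t/decay), 0 before onset."""
        t = np.asarray(rel_time_s, float) - self.latency_s
        k = np.where(t >= 0.0,
                     -np.expm1(-np.maximum(t, 0.0) / self.rise_tau_s)
                     * np.exp(-np.maximum(t, 0.0) / self.decay_tau_s),
                     0.0)
        tp = self.peak_time_s - self.latency_s
        peak = -math.expm1(-tp / self.rise_tau_s) * math.exp(-tp / self.decay_tau_s)
        return k / peak


@dataclass
class ArtifactModel:
    """Shared slow-bleach and motion components plus per-channel noise.

    Motion models fluctuating fiber-coupling efficiency: a slow zero-mean
    fractional modulation applied to both channels' slow baselines, with
    ``motion_sd`` giving its amplitude in 465-channel fluorescence units.
    Bleach and motion enter both channels identically up to the fixed
    ``gain_405`` (default 1.0, making isosbestic subtraction exact in the
    noise-free limit; a mismatched gain exposes the method's residual-motion
    limitation). Only the 465 channel ever carries transients.
    """

    baseline_465: float = 100.0
    baseline_405: float = 70.0
    bleach_amplitude: float = 20.0
    bleach_tau_s: float = 600.0
    motion_sd: float = 0.5
    motion_lowpass_hz: float = 0.5
    noise_sd_465: float = 0.3
    noise_sd_405: float = 0.3
    gain_405: float = 1.0

    def __post_init__(self) -> None:
        if self.bleach_tau_s <= 0:
            raise ValueError("bleach_tau_s must be > 0")
        for name in ("motion_sd", "noise_sd_465", "noise_sd_405"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Exact record of what was injected into a synthetic session."""

    event_times: list[float] = field(default_factory=list)
    true_response_amplitudes: list[float] = field(default_factory=list)
    true_freezing_intervals: list[tuple[float, float]] = field(default_factory=list)
    n_clipped_samples: int = 0


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def make_schedule(config: SessionConfig, *, day: str = "day1",
                  condition: str = "control",
                  subject_id: str = "s0") -> EventSchedule:
    """Place ``n_cs`` tone CSs followed by ``n_shock`` foot shocks.

    The first onset falls one habituation period into the session;
    consecutive onsets are separated by draws from ``iti_range_s``
    (uniform). Raises :class:`ScheduleError` naming the first event that
    does not fit inside ``duration_s``.
    """
    rng = np.random.default_rng(config.seed)
    specs = ([("cs", config.cs_duration_s)] * config.n_cs
             + [("shock", config.shock_duration_s)] * config.n_shock)
    if not specs:
        return EventSchedule([])
    itis = rng.uniform(*config.iti_range_s, size=len(specs) - 1)
    events = []
    onset = config.habituation_s
    for i, (etype, dur) in enumerate(specs):
        if onset + dur > config.duration_s:
            raise ScheduleError(
                f"event {i} ({etype}) at {onset:.1f}s does not fit in a "
                f"{config.duration_s:.1f}s session")
        events.append(Event(onset, onset + dur, etype, day=day,
                            condition=condition, subject_id=subject_id))
        if i < len(specs) - 1:
            onset += itis[i]
    return EventSchedule(events)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _lowpass_noise(rng: np.random.Generator, n: int, rate_hz: float,
                   cutoff_hz: float, sd: float) -> np.ndarray:
    """Gaussian noise low-pass filtered at ``cutoff_hz``, rescaled to ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    nyq = rate_hz / 2.0
    if cutoff_hz >= nyq:
        return sd * white
    b, a = sps.butter(2, cutoff_hz / nyq)
    slow = sps.filtfilt(b, a, white)
    s = slow.std()
    return slow * (sd / s) if s > 0 else slow


def render_recording(schedule: EventSchedule, transients: TransientModel,
                     artifacts: ArtifactModel, config: SessionConfig,
                     ) -> tuple[TwoChannelRecording, GroundTruth]:
    """Render the two fluorescence channels for a scheduled session.

    The slow baseline of the 465 channel is ``baseline_465 + bleach(t)``;
    each event contributes ``amplitude_i * kernel(t - onset_i)`` of dF/F on
    top of that slow baseline (so the injected amplitude is the true dF/F
    peak regardless of bleach state). Motion modulates both channels
    fractionally (scaled by ``gain_405`` in the 405 channel); the 405
    channel carries the shared bleach and motion but no transients.
    """
    for ev in schedule:
        if ev.offset_s > config.duration_s:
            raise ScheduleError(
                f"event at {ev.onset_s:.1f}s extends past session end")
    rng = np.random.default_rng(config.seed)
    t = config.time_axis()
    n = len(t)

    amplitudes = np.maximum(
        rng.normal(transients.amplitude, transients.amplitude_jitter_sd,
                   size=len(schedule)), 0.0)
    motion = _lowpass_noise(rng, n, config.sampling_rate_hz,
                            artifacts.motion_lowpass_hz, artifacts.motion_sd)
    noise465 = (rng.standard_normal(n) * artifacts.noise_sd_465
                if artifacts.noise_sd_465 > 0 else np.zeros(n))
    noise405 = (rng.standard_normal(n) * artifacts.noise_sd_405
                if artifacts.noise_sd_405 > 0 else np.zeros(n))

    bleach = artifacts.bleach_amplitude * np.exp(-t / artifacts.bleach_tau_s)
    slow465 = artifacts.baseline_465 + bleach

    dff_true = np.zeros(n)
    truth = GroundTruth()
    for ev, amp in zip(schedule, amplitudes):
        dff_true += amp * transients.kernel(t - ev.onset_s)
        truth.event_times.append(ev.onset_s)
        truth.true_response_amplitudes.append(float(amp))

    frac_motion = motion / artifacts.baseline_465
    slow405 = artifacts.baseline_405 + artifacts.gain_405 * bleach
    f465 = slow465 * (1.0 + dff_true + frac_motion) + noise465
    f405 = slow405 * (1.0 + artifacts.gain_405 * frac_motion) + noise405

    clipped = int(np.sum(f465 < 0) + np.sum(f405 < 0))
    if clipped:
        f465 = np.maximum(f465, 0.0)
        f405 = np.maximum(f405, 0.0)
    truth.n_clipped_samples = clipped

    rec = TwoChannelRecording(t, f465, f405,
                              sampling_rate_hz=config.sampling_rate_hz)
    return rec, truth


def render_movement(true_freezing_intervals: list[tuple[float, float]],
                    config: SessionConfig, moving_level: float = 120.0,
                    frozen_level: float = 30.0,
                    noise_sd: float = 0.0) -> MovementTrace:
    """Movement-score trace: ``frozen_level`` inside the given intervals,
    ``moving_level`` elsewhere, plus optional Gaussian noise."""
    rng = np.random.default_rng(config.seed + 1)
    t = config.time_axis()
    score = np.full(len(t), float(moving_level))
    for start, end in true_freezing_intervals:
        score[(t >= start) & (t < end)] = frozen_level
    if noise_sd > 0:
        score = score + rng.standard_normal(len(t)) * noise_sd
    return MovementTrace(t, score, sampling_rate_hz=config.sampling_rate_hz)
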