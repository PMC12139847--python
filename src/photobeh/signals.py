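"""Raw fluorescence to artifact-corrected z-score traces.

The chain is: per-channel dF/F against a least-squares slow-trend control
trace F0, isosbestic correction by plain subtraction of the 405 nm dF/F from
the 465 nm dF/F, then standardization to z-scores using the mean and standard
deviation of the full-session corrected trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .session_io import TwoChannelRecording

log = logging.getLogger("photobeh")

F0_MODELS = ("exponential_plus_constant", "polynomial")


@dataclass
class DffTrace:
    """Normalized fluorescence change (F - F0)/F0 for one channel."""

    time_s: np.ndarray
    dff: np.ndarray
    channel_label: str  # "465", "405" or "corrected"
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.dff = np.asarray(self.dff, float)
        if len(self.time_s) != len(self.dff):
            raise ValueError("dff length differs from time base")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")


@dataclass
class ZTrace:
    """Session-standardized trace: zero mean, unit SD over the full session."""

    time_s: np.ndarray
    z: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.z = np.asarray(self.z, float)
        if len(self.time_s) != len(self.z):
            raise ValueError("z length differs from time base")


def _exp_plus_const(t, a, tau, b):
    return a * np.exp(-t / tau) + b


def fit_control_trace(time_s: np.ndarray, f: np.ndarray,
                      model: str = "exponential_plus_constant",
                      poly_degree: int = 2) -> np.ndarray:
    """Least-squares slow-trend control trace F0 for one channel.

    ``model`` is either a single decaying exponential plus a constant
    (photobleaching physics) or a polynomial of ``poly_degree``. A
    non-convergent exponential fit falls back to the quadratic polynomial;
    either way the returned F0 never fits worse (in residual sum of squares)
    than the best constant.
    """
    time_s = np.asarray(time_s, float)
    f = np.asarray(f, float)
    if model not in F0_MODELS:
        raise ValueError(f"unknown F0 model {model!r}; choose from {F0_MODELS}")
    n_params = 3 if model == "exponential_plus_constant" else poly_degree + 1
    if len(f) < 10 * n_params:
        raise ValueError(
            f"trace of {len(f)} samples too short for a {n_params}-parameter fit")
    if not np.any(f > 0):
        raise ValueError("trace is nonpositive everywhere")

    if np.ptp(f) == 0.0:
        return np.full_like(f, f[0])

    def _poly(deg: int) -> np.ndarray:
        coeffs = np.polynomial.polynomial.polyfit(time_s, f, deg)
        return np.polynomial.polynomial.polyval(time_s, coeffs)

    if model == "polynomial":
        return _poly(poly_degree)

    span = time_s[-1] - time_s[0]
    p0 = (f[0] - f[-1], max(span / 3.0, 1e-6), f[-1])
    try:
        popt, _ = curve_fit(_exp_plus_const, time_s, f, p0=p0,
                            bounds=([-np.inf, 1e-9, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=10000)
        f0 = _exp_plus_const(time_s, *popt)
    except (RuntimeError, ValueError):
        log.warning("exponential F0 fit did not converge; "
                    "falling back to quadratic polynomial")
        return _poly(2)
    rss_exp = float(np.sum((f - f0) ** 2))
    rss_const = float(np.sum((f - f.mean()) ** 2))
    if rss_exp > rss_const:
        log.warning("exponential F0 fit worse than constant; "
                    "falling back to quadratic polynomial")
        return _poly(2)
    return f0


def compute_dff(rec_time_s: np.ndarray, f: np.ndarray, f0: np.ndarray,
                channel_label: str, sampling_rate_hz: float) -> DffTrace:
    """Pointwise dF/F = (F(t) - F0(t)) / F0(t)."""
    f = np.asarray(f, float)
    f0 = np.asarray(f0, float)
    if f.shape != f0.shape:
        raise ValueError("F and F0 shapes differ")
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        t_bad = np.asarray(rec_time_s, float)[bad[0]]
        raise ValueError(f"F0 <= 0 at t={t_bad:.3f}s; dF/F undefined")
    return DffTrace(rec_time_s, (f - f0) / f0, channel_label, sampling_rate_hz)


def isosbestic_correct(dff465: DffTrace, dff405: DffTrace) -> DffTrace:
    """Subtract the isosbestic-channel dF/F from the signal-channel dF/F.

    Plain pointwise subtraction, no scaling or regression: the shared
    motion/bleach/autofluorescence artifacts cancel to the extent the two
    channels carry them with equal gain.
    """
    if len(dff465.time_s) != len(dff405.time_s) or not np.allclose(
            dff465.time_s, dff405.time_s, atol=1e-9):
        raise ValueError("channel time bases differ")
    return DffTrace(dff465.time_s, dff465.dff - dff405.dff, "corrected",
                    dff465.sampling_rate_hz)


def standardize(dff: DffTrace) -> ZTrace:
    """z(t) = (dff(t) - mu) / sigma over the full session (population SD)."""
    mu = float(dff.dff.mean())
    sigma = float(dff.dff.std())  # population (ddof=0); immaterial at n >> 1
    if sigma == 0.0:
        raise ValueError("constant dF/F trace: z-score undefined (sigma = 0)")
    return ZTrace(dff.time_s, (dff.dff - mu) / sigma, dff.sampling_rate_hz)


def preprocess_recording(rec: TwoChannelRecording,
                         f0_model: str = "exponential_plus_constant",
                         ) -> tuple[ZTrace, DffTrace]:
    """Full chain for one recording: per-channel F0 fit and dF/F,
    isosbestic subtraction, then session z-scoring.

    Returns the z-trace and the corrected dF/F trace (useful when results
    are needed in dF/F units, e.g. amplitude recovery checks).
    """
    f0_465 = fit_control_trace(rec.time_s, rec.f465, f0_model)
    f0_405 = fit_control_trace(rec.time_s, rec.f405, f0_model)
    dff465 = compute_dff(rec.time_s, rec.f465, f0_465, "465",
                         rec.sampling_rate_hz)
    dff405 = compute_dff(rec.time_s, rec.f405, f0_405, "405",
                         rec.sampling_rate_hz)
    corrected = isosbestic_correct(dff465, dff405)
    return standardize(corrected), corrected
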