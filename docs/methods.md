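# Methods

`photobeh` quantifies event-locked calcium signals from two-channel fiber
photometry recorded during auditory conditioning, and freezing behavior from
movement-score traces. This note documents the models, the constants, the
numerical choices, and what the synthetic test bed does and does not
establish.

## Signal model and preprocessing

A recording consists of a calcium-dependent channel (465 nm excitation,
`f465`) and an isosbestic control channel (405 nm, `f405`) sampled on one
uniform time base. The control channel reflects calcium-independent
fluorescence — photobleaching, fiber-coupling (motion) fluctuations,
autofluorescence — and is used to remove those artifacts from the signal
channel.

Each channel is first converted to a normalized fluorescence change

    dF/F(t) = (F(t) − F0(t)) / F0(t)

where `F0` is a slow-trend control trace obtained by least squares on the
full session. The default `F0` model is a single decaying exponential plus a
constant, `a·exp(−t/τ) + b`, which is the photobleaching form; a quadratic
polynomial is available behind a switch and is used automatically if the
exponential fit fails to converge or fits worse than a constant. The
functional form only has to capture trends much slower than the transients;
whatever slow structure it misses is also present in the 405 nm channel and
is removed at the next step.

Artifact correction is plain subtraction of the control-channel dF/F from
the signal-channel dF/F, with no fitted scaling between channels. This
cancels shared *fractional* fluctuations exactly when both channels carry
them with equal gain; a gain mismatch leaves residual motion power, which
the test suite demonstrates rather than hides.

The corrected trace is standardized to z-scores using the mean and standard
deviation of the **whole session** (population SD; at session lengths of
10⁴–10⁵ samples the n vs n−1 distinction is far below every tolerance used
anywhere in the package, and the population form keeps the ZTrace invariant
exact). Standardization happens once per subject per session, before any
epoching, so trials within a session share one scale.

## Peri-event analysis

Epochs are cut on the recording's own grid. Time uses half-open
`[onset, offset)` event semantics, and the sample at relative time 0 is the
first sample at-or-after onset, so boundary samples are never counted twice.
Default windows:

| event       | window (s)   | baseline (s) |
|-------------|--------------|--------------|
| tone CS     | −20 … +40    | [−20, 0)     |
| foot shock  | −5 … +10     | [−5, 0)      |

The baseline (preCS or pre-event) mean is subtracted from every point of the
trial. Averaging is two-stage: trials → subject mean → unweighted group
mean, so a subject with more usable trials never dominates the group trace.

AUC over a named interval is the composite trapezoid over the grid samples
inside the interval, with the interval endpoints linearly interpolated when
they fall between samples. This makes the area exact for piecewise-linear
waveforms, additive over contiguous splits to 1e−9, and first-order
independent of the sampling-rate choice. Default named intervals: full CS
0–20 s, CS onset 0–2 s, and an offset window 20–25 s. The offset window's
bounds are this package's choice — the post-cue component it captures has no
canonical numeric definition — and are configurable.

## Bootstrapped waveform analysis

The unit of resampling is the **subject-level mean waveform**. For each of
`n_boot` (default 1000) iterations, `n` whole waveforms are drawn with
replacement from the `n` subjects and averaged; resampling whole waveforms
jointly preserves each subject's time autocorrelation. Pointwise 95% limits
are the 2.5/97.5 percentiles of the bootstrap-mean distribution. Each
half-width, measured about the bootstrap-distribution mean, is then expanded
by `n/(n−1)` to counter the narrowness bias of percentile intervals at small
n. (Centering the expansion on the point estimate instead changes measured
coverage by less than Monte-Carlo error; the bootstrap-mean centering is the
implemented default.)

A **significant transient** is a maximal run of samples where the band
excludes zero, the group mean additionally exceeds ±0.5 z, and the run lasts
at least 1/3 s. The minimum run is `ceil(min_run_s · rate)` whole samples —
conservative and rate-independent — and a run of k samples is scored as
k/rate seconds. At the default 30 Hz analysis rate the 1/3 s rule is exactly
10 samples.

Between-condition comparisons bootstrap the difference waveform: paired mode
resamples within-subject difference waveforms (subjects must match row for
row); unpaired mode resamples each group independently and uses
`n = min(nA, nB)` in the expansion. The run rule applies without the ±0.5
magnitude threshold, which belongs to the vs-zero test only. No p-values are
emitted anywhere: the outputs are bands and run intervals.

Calibration, measured by this package's own Monte-Carlo battery (Gaussian
subject values, one time point, 2000 datasets × 1000 resamples): the
expanded interval covers the true mean ≈92% of the time at n=10 and ≈90% at
n=5, versus ≈89% and ≈84% unexpanded. The `n/(n−1)` factor (1.11 at n=10)
narrows but does not close the gap to nominal 95% — exact correction at
n=10 would need a factor near t₉/z ≈ 1.15. Users should read the bands as
mildly anti-conservative at very small n; the expansion is kept as the
method's defining convention.

## Freezing detection

Freezing is scored from an arbitrary-unit movement score (larger = more
movement) with a hysteresis criterion: a candidate bout opens at the first
sample strictly below the onset threshold (60) and is confirmed once the
sub-threshold condition has held continuously for the minimum duration
(2 s); any sample at or above 60 before confirmation cancels the candidate.
A confirmed bout is scored retroactively from the candidate onset and
persists until the first sample strictly above the offset threshold (70), so
wobbles inside the 60–70 band never fragment a bout. Boundary-equal samples
continue the current state. Whether the 2 s confirmation requires sub-60
throughout (implemented) or merely sub-70 after a sub-60 entry is a genuine
ambiguity; the stricter reading was chosen and the detector's unit tests pin
it.

Percent freezing over an epoch clips bouts to the epoch boundaries; the
CS-minus-preCS contrast averages per-trial differences within subject, then
across subjects, mirroring the two-stage waveform averaging. The −60 shift
of movement traces is presentation-only and never feeds detection.

## Synthetic sessions

The generator produces the study conditions the analysis is built for:
sessions with 4 tone CSs (20 s) and optional foot shocks (2 s) separated by
pseudo-random 70–120 s intervals after a 120 s habituation, at a 30 Hz
analysis rate (chosen so the 1/3 s rule is an integer number of samples;
configurable).

The 465 channel is
`(baseline + bleach(t)) · (1 + Σᵢ aᵢ·k(t−tᵢ) + μ(t)) + noise`, where

* `k` is a peak-normalized double-exponential kernel
  `(1 − e^(−t/τ_rise))·e^(−t/τ_decay)` with fast-GCaMP-like defaults
  τ_rise = 0.1 s, τ_decay = 0.8 s. These kinetics are placeholders for the
  indicator's true in-vivo constants, which are cell-type dependent and not
  pinned by any input to this package.
* per-event amplitudes `aᵢ ~ N(amplitude, jitter²)` truncated at 0
  (responses modeled as non-negative), in true dF/F units — the transient is
  scaled by the instantaneous slow baseline, so the injected amplitude *is*
  the ground-truth dF/F peak regardless of bleach state. Default 0.05.
* `bleach(t)` is a 20-unit exponential with τ = 600 s on a 100-unit
  baseline, and `μ(t)` is zero-mean fractional motion (coupling-efficiency
  fluctuation), low-pass filtered at 0.5 Hz, shared by both channels up to a
  configurable gain (default 1, making isosbestic subtraction exact in the
  noise-free limit).
* white per-sample noise, default SD 0.3 fluorescence units per channel
  (≈0.3% of baseline — a clean but realistic recording).

The 405 channel carries the same bleach and motion (times the gain) on a
70-unit baseline and never carries transients. Movement traces are two-level
step functions (moving ≈120, frozen ≈30, i.e. clear of both thresholds) plus
Gaussian noise, with every freezing interval recorded in the ground truth.

One seeded generator drives each session, with draws in a fixed order
(intervals, amplitudes, motion, 465 noise, 405 noise), so a seed pins the
session exactly. Experiment-level cohorts derive per-subject seeds from a
stable hash of the subject id, so enlarging a cohort never changes existing
subjects' data.

**What the generator does not emulate:** hemodynamic contamination,
wavelength-dependent motion gain (beyond the single scalar), sensor
nonlinearity and saturation, session-to-session expression drift,
non-Gaussian movement scores, or correlated photon (shot) noise. Passing
tests therefore establish the *analysis chain's* correctness and
calibration, not robustness to every artifact class real recordings can
contain.

## Numerical and degenerate-input choices

* Exponential `F0` fits run with positivity-bounded τ and fall back to the
  quadratic polynomial on non-convergence or when beaten by a constant fit;
  either path guarantees RSS ≤ the best constant.
* `dF/F` raises on any `F0 ≤ 0`, naming the first offending time;
  z-scoring raises on a constant trace (σ = 0).
* Trials whose window leaves the recording are dropped and counted; zero
  retained trials is an error, as is an empty baseline window.
* Bootstrap bands require ≥2 subjects; a single-subject condition degrades
  to a mean-only output with an explicit note row.
* Bout gaps shorter than one sample period are merged; bout boundary
  ties resolve toward state persistence.
* All tolerances asserted in tests: 1e−9 for algebraic identities
  (AUC additivity, baseline-mean-zero, z moments), 1% for noise-free model
  refits, 10% for full-chain amplitude recovery at default noise.

## Problem sizes used in the validation battery

Coverage: 2000 Monte-Carlo datasets × 1000 resamples at one time point.
Type-I error: 500 simulated two-group comparisons (n=8 per group, 5 s
windows, 1000 resamples). Parameter recovery and artifact-only masks: 8
subjects × 4 trials of 600 s sessions. Structure experiment: 3 conditions ×
6 subjects × 2 days. These sizes give Monte-Carlo error comfortably below
each check's tolerance while keeping the whole battery around ten seconds.
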