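"""End-to-end orchestration for multi-subject, multi-condition experiments.

A session bundles one subject's recording, event schedule and movement
trace for one day; an experiment is a list of sessions plus a
:class:`~photobeh.config.RunConfig`. :func:`run_experiment` runs the full
chain — preprocess, epoch, baseline-normalize, bootstrap stats,
between-condition comparisons, freezing — grouped by (condition, day,
event type), and returns long-format tables plus a manifest.

Seeding: the experiment seed is combined with a stable hash of each
subject id to derive per-subject generator seeds, so adding a subject
never perturbs the others' synthetic data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (BootstrapSettings, SignificanceMask, bootstrap_ci,
                        compare_waveforms, significant_runs)
from .config import RunConfig
from .freezing import contrast_cs_precs, detect_freezing, percent_freezing
from .perievent import (PeriEventTensor, auc, baseline_normalize,
                        extract_epochs, stack_subject_means, subject_mean)
from .session_io import (EventSchedule, MovementTrace, TwoChannelRecording,
                         write_results)
from .signals import preprocess_recording
from .synthetic import (ArtifactModel, SessionConfig, TransientModel,
                        make_schedule, render_movement, render_recording)

log = logging.getLogger("photobeh")


def child_seed(experiment_seed: int, subject_id: str, salt: str = "") -> int:
    """Stable per-subject seed below 2**31."""
    h = zlib.crc32(f"{subject_id}|{salt}".encode())
    return (experiment_seed * 2654435761 + h) % (2 ** 31)


@dataclass
class SessionData:
    """One subject-day bundle of raw inputs."""

    subject_id: str
    condition: str
    day: str
    recording: TwoChannelRecording
    schedule: EventSchedule
    movement: MovementTrace | None = None


@dataclass
class Experiment:
    sessions: list[SessionData]
    config: RunConfig = field(default_factory=RunConfig)

    def __post_init__(self) -> None:
        conds = {s.condition for s in self.sessions}
        bad = conds - {"safety", "threat", "control"}
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")


# ---------------------------------------------------------------------------
# synthetic experiments
# ---------------------------------------------------------------------------

@dataclass
class ConditionDesign:
    """Per-day response model for one training condition.

    ``amplitude_by_day`` maps day labels to true CS-evoked dF/F peak
    amplitudes; ``decay_tau_s`` controls whether the response is an
    onset-locked transient (sub-second decay) or sustained over the cue
    (decay on the order of the cue length). ``freezing`` maps day labels to
    (precs_frozen, cs_frozen) flags controlling where movement-trace
    freezing bouts are placed relative to each CS.
    """

    amplitude_by_day: dict[str, float]
    decay_tau_s: float = 0.8
    rise_tau_s: float = 0.1
    amplitude_jitter_sd: float = 0.005
    freezing: dict[str, tuple[bool, bool]] = field(default_factory=dict)


def simulate_experiment(designs: dict[str, ConditionDesign],
                        n_subjects: int, seed: int,
                        config: RunConfig | None = None,
                        n_cs: int = 4, duration_s: float = 600.0,
                        artifacts: ArtifactModel | None = None,
                        ) -> Experiment:
    """Generate a multi-condition experiment with known ground truth.

    One session per (condition, subject, day); subjects are named
    ``<condition>_<k>`` and their generator seeds derive from ``seed`` and
    the subject id, so the cohort is reproducible and extensible.
    """
    config = config or RunConfig(seed=seed)
    artifacts = artifacts or ArtifactModel()
    sessions: list[SessionData] = []
    for condition, design in designs.items():
        for k in range(n_subjects):
            subject_id = f"{condition}_{k}"
            for day, amp in design.amplitude_by_day.items():
                scfg = SessionConfig(
                    duration_s=duration_s, n_cs=n_cs,
                    sampling_rate_hz=config.sampling_rate_hz,
                    seed=child_seed(seed, subject_id, salt=day))
                schedule = make_schedule(scfg, day=day, condition=condition,
                                         subject_id=subject_id)
                tmodel = TransientModel(
                    rise_tau_s=design.rise_tau_s,
                    decay_tau_s=design.decay_tau_s, amplitude=amp,
                    amplitude_jitter_sd=design.amplitude_jitter_sd)
                rec, _truth = render_recording(schedule, tmodel, artifacts,
                                               scfg)
                movement = None
                if day in design.freezing:
                    precs_frozen, cs_frozen = design.freezing[day]
                    intervals = []
                    for ev in schedule.of_type("cs"):
                        if precs_frozen:
                            intervals.append((ev.onset_s - 20.0, ev.onset_s))
                        if cs_frozen:
                            intervals.append((ev.onset_s, ev.offset_s))
                    movement = render_movement(intervals, scfg, noise_sd=2.0)
                sessions.append(SessionData(subject_id, condition, day,
                                            rec, schedule, movement))
    return Experiment(sessions, config)


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

def _mask_rows(mask: SignificanceMask, comparison_id: str) -> list[dict]:
    return [{"comparison_id": comparison_id, "start_s": s, "end_s": e,
             "sign": sign} for s, e, sign in mask.runs]


def run_experiment(experiment: Experiment,
                   out_dir: str | None = None) -> dict[str, pd.DataFrame]:
    """Run the full analysis and return the results tables.

    Tables: ``waveforms`` (group mean +/- CI per condition/day/event type),
    ``significance_runs`` (vs-zero and condition-vs-control masks),
    ``auc`` (per subject and interval), ``freezing`` (per subject per day),
    ``freezing_contrast`` (per subject CS-preCS), and a ``manifest`` JSON
    is written when ``out_dir`` is given.
    """
    cfg = experiment.config
    settings = BootstrapSettings(n_boot=cfg.n_boot, alpha=cfg.alpha,
                                 threshold=cfg.threshold,
                                 min_run_s=cfg.min_run_s, expand=cfg.expand,
                                 seed=cfg.seed)

    # -- preprocess every session once
    ztraces: dict[int, object] = {}
    for i, ses in enumerate(experiment.sessions):
        try:
            ztraces[i], _ = preprocess_recording(ses.recording, cfg.f0_model)
        except Exception as exc:
            raise RuntimeError(
                f"preprocess failed for subject {ses.subject_id} "
                f"({ses.condition}/{ses.day}): {exc}") from exc

    # -- group sessions by (condition, day, event_type)
    groups: dict[tuple[str, str, str], list[tuple[SessionData, PeriEventTensor]]] = {}
    for i, ses in enumerate(experiment.sessions):
        for etype in sorted({e.event_type for e in ses.schedule}):
            if etype not in cfg.windows:
                continue
            try:
                tensor = extract_epochs(ztraces[i], ses.schedule, etype,
                                        cfg.windows[etype],
                                        subject_id=ses.subject_id)
                tensor = baseline_normalize(tensor, cfg.baselines[etype])
            except ValueError as exc:
                raise RuntimeError(
                    f"epoching failed for subject {ses.subject_id} "
                    f"({ses.condition}/{ses.day}/{etype}): {exc}") from exc
            groups.setdefault((ses.condition, ses.day, etype), []).append(
                (ses, tensor))

    wave_rows, run_rows, auc_rows, note_rows = [], [], [], []
    group_means: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (condition, day, etype), items in sorted(groups.items()):
        tensors = [t for _, t in items]
        rel_time = tensors[0].rel_time_s
        per_subject = stack_subject_means(tensors)
        group_means[(condition, day, etype)] = (rel_time, per_subject)
        gid = f"{condition}/{day}/{etype}"
        if per_subject.shape[0] >= 2:
            summary = bootstrap_ci(per_subject, rel_time, settings)
            mask = significant_runs(summary, settings)
            run_rows.extend(_mask_rows(mask, f"{gid}/vs0"))
            for j, rt in enumerate(rel_time):
                wave_rows.append({
                    "condition": condition, "day": day, "event_type": etype,
                    "rel_time_s": rt, "mean": summary.mean[j],
                    "ci_lo": summary.ci_lo[j], "ci_hi": summary.ci_hi[j],
                    "n_subjects": summary.n_subjects})
        else:
            note_rows.append({"group": gid,
                              "note": "ci_not_computable_single_subject"})
            gm = per_subject.mean(axis=0)
            for j, rt in enumerate(rel_time):
                wave_rows.append({
                    "condition": condition, "day": day, "event_type": etype,
                    "rel_time_s": rt, "mean": gm[j],
                    "ci_lo": np.nan, "ci_hi": np.nan, "n_subjects": 1})
        # per-subject AUCs over the configured named intervals
        for _, tensor in items:
            wf = subject_mean(tensor)
            for name, a, b in cfg.auc_intervals:
                if a < rel_time[0] or b > rel_time[-1]:
                    continue
                res = auc(rel_time, wf, (a, b), interval_name=name,
                          subject_id=tensor.subject_id)
                auc_rows.append({
                    "condition": condition, "day": day, "event_type": etype,
                    "subject_id": res.subject_id, "interval_name": name,
                    "start_s": res.start_s, "end_s": res.end_s,
                    "auc": res.auc})

    # -- condition-vs-control comparisons, matched on (day, event_type)
    for (condition, day, etype), (rel_time, w_a) in sorted(group_means.items()):
        if condition == "control":
            continue
        key = ("control", day, etype)
        if key not in group_means:
            continue
        _, w_b = group_means[key]
        if w_a.shape[0] < 2 or w_b.shape[0] < 2:
            continue
        _, mask = compare_waveforms(w_a, w_b, rel_time, settings,
                                    paired=False)
        run_rows.extend(
            _mask_rows(mask, f"{condition}_vs_control/{day}/{etype}"))

    # -- freezing
    freeze_rows, contrast_trial_rows = [], []
    for ses in experiment.sessions:
        if ses.movement is None:
            continue
        bouts = detect_freezing(ses.movement, cfg.onset_thr, cfg.offset_thr,
                                cfg.min_dur_s)
        for k, ev in enumerate(ses.schedule.of_type("cs")):
            precs = percent_freezing(bouts, (ev.onset_s - 20.0, ev.onset_s))
            cs = percent_freezing(bouts, (ev.onset_s, ev.offset_s))
            contrast_trial_rows.append({
                "condition": ses.condition, "day": ses.day,
                "subject_id": ses.subject_id, "trial": k,
                "precs_percent": precs, "cs_percent": cs})
        session_pct = percent_freezing(
            bouts, (float(ses.movement.time_s[0]),
                    float(ses.movement.time_s[-1])
                    + 1.0 / ses.movement.sampling_rate_hz))
        freeze_rows.append({"condition": ses.condition, "day": ses.day,
                            "subject_id": ses.subject_id,
                            "epoch_name": "session",
                            "percent_freezing": session_pct})

    tables: dict[str, pd.DataFrame] = {
        "waveforms": pd.DataFrame(wave_rows),
        "significance_runs": pd.DataFrame(
            run_rows, columns=["comparison_id", "start_s", "end_s", "sign"]),
        "auc": pd.DataFrame(auc_rows),
        "freezing": pd.DataFrame(freeze_rows),
        "notes": pd.DataFrame(note_rows, columns=["group", "note"]),
    }
    if contrast_trial_rows:
        trial_df = pd.DataFrame(contrast_trial_rows)
        contrasts = []
        for (cond, day), sub in trial_df.groupby(["condition", "day"]):
            c = contrast_cs_precs(sub)
            c.insert(0, "day", day)
            c.insert(0, "condition", cond)
            contrasts.append(c)
        tables["freezing_trials"] = trial_df
        tables["freezing_contrast"] = pd.concat(contrasts, ignore_index=True)

    if out_dir is not None:
        paths = write_results(tables, out_dir)
        manifest = {
            "photobeh_version": __version__,
            "numpy_version": np.__version__,
            "seed": cfg.seed,
            "n_sessions": len(experiment.sessions),
            "config": {k: v for k, v in vars(cfg).items()
                       if isinstance(v, (int, float, str, bool))},
            "table_sha256": {name: hashlib.sha256(
                p.read_bytes()).hexdigest() for name, p in paths.items()},
        }
        with open(f"{out_dir}/manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return tables
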