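#!/usr/bin/env python
"""Generate a small synthetic cohort and write it as delimited text.

Creates one conditioning-day session per subject for a safety-style cohort
(4 tone CSs of 20 s at pseudo-random 70-120 s intervals, GCaMP6f-like
transients of 0.05 dF/F, shared bleach/motion artifacts) plus a movement
trace with freezing bouts before each CS, and writes everything under
results/sessions/ together with the ground-truth sidecars.
"""

import sys
from pathlib import Path

import pandas as pd

from photobeh.pipeline import child_seed
from photobeh.session_io import (write_movement, write_recording,
                                 write_schedule)
from photobeh.synthetic import (ArtifactModel, SessionConfig, TransientModel,
                                make_schedule, render_movement,
                                render_recording)

OUT = Path("results/sessions")
N_SUBJECTS = 4
SEED = 42


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    tm = TransientModel(amplitude=0.05, amplitude_jitter_sd=0.005)
    art = ArtifactModel()
    for k in range(N_SUBJECTS):
        subject = f"safety_{k}"
        cfg = SessionConfig(duration_s=600.0, n_cs=4,
                            seed=child_seed(SEED, subject, "day1"))
        sch = make_schedule(cfg, day="day1", condition="safety",
                            subject_id=subject)
        rec, truth = render_recording(sch, tm, art, cfg)
        freezing = [(ev.onset_s - 20.0, ev.onset_s)
                    for ev in sch.of_type("cs")]
        mv = render_movement(freezing, cfg, noise_sd=2.0)
        base = OUT / subject
        write_recording(rec, f"{base}.recording.csv")
        write_schedule(sch, f"{base}.schedule.csv")
        write_movement(mv, f"{base}.movement.csv")
        pd.DataFrame({"event_time_s": truth.event_times,
                      "true_amplitude": truth.true_response_amplitudes}
                     ).to_csv(f"{base}.ground_truth.csv", index=False)
        print(f"{subject}: {len(rec)} samples, {len(sch)} events, "
              f"{len(freezing)} freezing intervals -> {base}.*.csv")
    print(f"\nwrote {N_SUBJECTS} sessions under {OUT}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
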