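#!/usr/bin/env python
"""Freezing-bout detection and the CS-minus-preCS contrast.

Applies the hysteresis criterion (onset: movement score below 60 sustained
for 2 s; offset: score above 70) to each simulated movement trace, then
measures percent freezing in each 20 s preCS and CS epoch and averages the
per-trial CS-minus-preCS difference within and then across subjects.
"""

import sys
from pathlib import Path

import pandas as pd

from photobeh.freezing import (contrast_cs_precs, detect_freezing,
                               percent_freezing)
from photobeh.session_io import read_movement, read_schedule

SESSIONS = Path("results/sessions")
OUT = Path("results")


def main() -> int:
    if not SESSIONS.exists():
        print("run analysis/01_simulate_sessions.py first", file=sys.stderr)
        return 1
    rows, bout_rows = [], []
    for mv_path in sorted(SESSIONS.glob("*.movement.csv")):
        subject = mv_path.name.replace(".movement.csv", "")
        trace = read_movement(mv_path)
        sch = read_schedule(SESSIONS / f"{subject}.schedule.csv")
        bouts = detect_freezing(trace)
        bout_rows.extend({"subject_id": subject, "start_s": b.start_s,
                          "end_s": b.end_s} for b in bouts)
        for k, ev in enumerate(sch.of_type("cs")):
            rows.append({
                "subject_id": subject, "trial": k,
                "precs_percent": percent_freezing(
                    bouts, (ev.onset_s - 20.0, ev.onset_s)),
                "cs_percent": percent_freezing(
                    bouts, (ev.onset_s, ev.offset_s))})
        print(f"{subject}: {len(bouts)} bouts, "
              f"total {sum(b.duration_s for b in bouts):.1f} s frozen")

    trial_df = pd.DataFrame(rows)
    contrast = contrast_cs_precs(trial_df)
    trial_df.to_csv(OUT / "freezing_trials.csv", index=False)
    pd.DataFrame(bout_rows).to_csv(OUT / "freezing_bouts.csv", index=False)
    contrast.to_csv(OUT / "freezing_contrast.csv", index=False)
    print(f"\ngroup CS-minus-preCS freezing: "
          f"{contrast['cs_minus_precs'].mean():+.1f} percentage points "
          f"(preCS {contrast['precs_percent'].mean():.1f}%, "
          f"CS {contrast['cs_percent'].mean():.1f}%)")
    print(f"wrote freezing tables under {OUT}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
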