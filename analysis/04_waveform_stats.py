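#!/usr/bin/env python
"""Group bootstrap confidence bands and significant transients.

Stacks the per-subject CS waveforms from 03_epoch_and_auc.py, resamples
subjects with replacement (1000 iterations), forms 95% percentile bands
expanded by n/(n-1), and reports every period where the band excludes zero
and the mean exceeds +/-0.5 z for at least 1/3 s.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from photobeh.bootstrap import (BootstrapSettings, bootstrap_ci,
                                significant_runs)

WAVEFORMS = Path("results/cs_waveforms.csv")
OUT = Path("results")
SEED = 42


def main() -> int:
    if not WAVEFORMS.exists():
        print("run analysis/03_epoch_and_auc.py first", file=sys.stderr)
        return 1
    df = pd.read_csv(WAVEFORMS)
    pivot = df.pivot(index="subject_id", columns="rel_time_s", values="z")
    rel_time = pivot.columns.to_numpy(float)
    w = pivot.to_numpy()

    settings = BootstrapSettings(n_boot=1000, seed=SEED)
    summary = bootstrap_ci(w, rel_time, settings)
    mask = significant_runs(summary, settings)

    pd.DataFrame({"rel_time_s": summary.rel_time_s, "mean": summary.mean,
                  "ci_lo": summary.ci_lo, "ci_hi": summary.ci_hi}
                 ).to_csv(OUT / "cs_waveform_summary.csv", index=False)
    pd.DataFrame([{"start_s": s, "end_s": e, "sign": g}
                  for s, e, g in mask.runs],
                 columns=["start_s", "end_s", "sign"]
                 ).to_csv(OUT / "cs_significant_runs.csv", index=False)

    print(f"{summary.n_subjects} subjects; peak group mean "
          f"{summary.mean.max():.2f} z at "
          f"t={rel_time[summary.mean.argmax()]:+.2f} s")
    if mask.runs:
        for s, e, g in mask.runs:
            print(f"significant transient ({g}): {s:+.2f} to {e:+.2f} s "
                  f"({e - s:.2f} s)")
    else:
        print("no significant transients")
    print(f"wrote {OUT}/cs_waveform_summary.csv and "
          f"{OUT}/cs_significant_runs.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
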