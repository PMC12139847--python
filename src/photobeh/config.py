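"""Run configuration: every fixed constant of the analysis in one place.

The defaults encode the study design this package targets: 20 s conditioned
stimuli epoched from 20 s before onset to 20 s after offset, 2 s foot shocks
epoched from 5 s before to 10 s after onset, pre-event baseline subtraction,
1000-iteration percentile bootstrap with n/(n-1) expansion, the 1/3 s
significant-run rule with a +/-0.5 z threshold, and 60/70 hysteresis freezing
thresholds with a 2 s minimum bout.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# (pre_s, post_s) relative to event onset, per event type
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "cs": (20.0, 40.0),
    "shock": (5.0, 10.0),
    "cs_offset_probe": (5.0, 10.0),
}

# baseline window [start_s, end_s) relative to onset, per event type
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "cs": (-20.0, 0.0),
    "shock": (-5.0, 0.0),
    "cs_offset_probe": (-5.0, 0.0),
}

# named AUC intervals in seconds relative to event onset
DEFAULT_AUC_INTERVALS: list[tuple[str, float, float]] = [
    ("cs_full", 0.0, 20.0),
    ("cs_onset", 0.0, 2.0),
    ("offset", 20.0, 25.0),
]


@dataclass
class RunConfig:
    """All tunable constants of the pipeline.

    Windows and baselines are keyed by event type; times are seconds relative
    to event onset. ``min_run_s`` is the minimum duration a confidence
    interval must exclude zero for a significant transient; ``threshold`` is
    the z-score magnitude the mean must additionally exceed.
    """

    sampling_rate_hz: float = 30.0
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS))
    baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES))
    auc_intervals: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_AUC_INTERVALS))
    # bootstrap settings
    n_boot: int = 1000
    alpha: float = 0.05
    threshold: float = 0.5
    min_run_s: float = 1.0 / 3.0
    expand: bool = True
    # freezing detection
    onset_thr: float = 60.0
    offset_thr: float = 70.0
    min_dur_s: float = 2.0
    # F0 model for dF/F
    f0_model: str = "exponential_plus_constant"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.min_run_s <= 0:
            raise ValueError("min_run_s must be > 0")
        if self.onset_thr >= self.offset_thr:
            raise ValueError(
                f"onset_thr ({self.onset_thr}) must be < offset_thr "
                f"({self.offset_thr})")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        for ev, (pre, post) in self.windows.items():
            if pre + post <= 0:
                raise ValueError(f"empty window for event type {ev!r}")

    # -- flat key/value (YAML) persistence -------------------------------

    _FLAT_KEYS = ("sampling_rate_hz", "n_boot", "alpha", "threshold",
                  "min_run_s", "expand", "onset_thr", "offset_thr",
                  "min_dur_s", "f0_model", "seed")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value config document; unknown keys warn,
        missing keys take the documented defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} is not a key/value document")
        kwargs = {}
        for key, val in raw.items():
            if key in cls._FLAT_KEYS:
                kwargs[key] = val
            elif key == "windows":
                kwargs["windows"] = {k: tuple(v) for k, v in val.items()}
            elif key == "baselines":
                kwargs["baselines"] = {k: tuple(v) for k, v in val.items()}
            elif key == "auc_intervals":
                kwargs["auc_intervals"] = [
                    (str(n), float(a), float(b)) for n, a, b in val]
            else:
                warnings.warn(f"unknown config key {key!r} ignored")
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["windows"] = {k: list(v) for k, v in self.windows.items()}
        doc["baselines"] = {k: list(v) for k, v in self.baselines.items()}
        doc["auc_intervals"] = [list(t) for t in self.auc_intervals]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
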