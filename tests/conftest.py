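import numpy as np
import pytest

from photobeh.session_io import MovementTrace
from photobeh.synthetic import (ArtifactModel, SessionConfig, TransientModel,
                                make_schedule, render_recording)

RATE = 30.0


@pytest.fixture(scope="session")
def quiet_session():
    """A noise-free 4-CS session: the analytic reference for the chain."""
    cfg = SessionConfig(duration_s=600.0, n_cs=4, seed=11)
    schedule = make_schedule(cfg)
    artifacts = ArtifactModel(motion_sd=0.0, noise_sd_465=0.0,
                              noise_sd_405=0.0)
    transients = TransientModel(amplitude=0.05, amplitude_jitter_sd=0.0)
    rec, truth = render_recording(schedule, transients, artifacts, cfg)
    return cfg, schedule, transients, artifacts, rec, truth


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise session with shared motion artifact."""
    cfg = SessionConfig(duration_s=600.0, n_cs=4, seed=7)
    schedule = make_schedule(cfg)
    rec, truth = render_recording(schedule, TransientModel(),
                                  ArtifactModel(), cfg)
    return cfg, schedule, rec, truth


def step_trace(segments, rate=RATE):
    """MovementTrace from (value, duration_s) segments."""
    vals = np.concatenate([np.full(int(round(d * rate)), v)
                           for v, d in segments])
    t = np.arange(len(vals)) / rate
    return MovementTrace(t, vals, sampling_rate_hz=rate)
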