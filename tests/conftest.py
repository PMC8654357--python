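import numpy as np
import pytest

from chophot.synth import SimConfig, TrialSchedule, simulate_session
from chophot.traces import DffTrace


@pytest.fixture(scope="session")
def short_session():
    """One 300 s synthetic session with default (study) conditions."""
    cfg = SimConfig(seed=11, duration_s=300.0)
    fluo, pupil, events, truth = simulate_session(cfg)
    return cfg, fluo, pupil, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_dff(values, fs=1017.0, t0=0.0, **kw):
    return DffTrace(fs=fs, dff=np.asarray(values, dtype=float), t0=t0, **kw)
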