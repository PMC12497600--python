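import numpy as np
import pytest

from pttsleep.ptt import BeatSeries


def make_dip_series(depth, fall, plateau=5.0, recovery=20.0, start=150.0,
                    baseline=250.0, total=400.0, dt=0.6):
    """Flat series with one scripted dip (linear fall, flat bottom, recovery)."""
    t = np.arange(0.0, total, dt)
    x = np.full_like(t, baseline)
    rel = t - start
    m = (rel >= 0) & (rel < fall)
    x[m] -= depth * rel[m] / fall
    m = (rel >= fall) & (rel < fall + plateau)
    x[m] -= depth
    m = (rel >= fall + plateau) & (rel < fall + plateau + recovery)
    x[m] -= depth * (1 - (rel[m] - fall - plateau) / recovery)
    return t, x


def make_beats(t, x, valid=None):
    if valid is None:
        valid = np.ones_like(t, dtype=bool)
    return BeatSeries(beat_time=np.asarray(t, float),
                      ptt_raw=np.asarray(x, float),
                      valid=np.asarray(valid, bool))


def make_desat_trace(total_s=3600, baseline=97.0, dips=()):
    """1 Hz SpO2 trace with rectangular dips given as (start, dur, depth)."""
    x = np.full(int(total_s), baseline)
    for start, dur, depth in dips:
        x[int(start):int(start + dur)] = baseline - depth
    return x


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
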