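import numpy as np
import pytest

from painsense import (
    ChannelName,
    MatchConfig,
    PainRecord,
    PainSource,
    SensorSegment,
    SensorStream,
    SessionBundle,
    SimConfig,
    generate_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stream(channel, n=180, hz=1.0, value=80.0, rng=None):
    """Constant-valued stream unless an rng is given (then N(value, 1))."""
    t = np.arange(n) / hz
    if rng is None:
        v = np.full(n, float(value))
    else:
        v = rng.normal(value, 1.0, size=n)
    if channel is ChannelName.STEPS:
        v = np.cumsum(np.abs(v)) / 10.0
    return SensorStream(channel=channel, timestamps=t, values=v)


@pytest.fixture
def full_bundle(rng):
    """Three full minutes of all 8 channels at 1 Hz, with two pain reports."""
    streams = {ch: make_stream(ch, n=180, rng=rng) for ch in ChannelName}
    pain = [
        PainRecord(time_min=0, score=7.0, source=PainSource.NURSE),
        PainRecord(time_min=2, score=6.5, source=PainSource.APP),
    ]
    return SessionBundle(session_id="T1", streams=streams, pain=pain)


def make_segment(values_by_channel, start_min=0, hz=1.0):
    """Build a SensorSegment from {channel: 1-d array} starting at start_min."""
    samples, times = {}, {}
    for ch, v in values_by_channel.items():
        v = np.asarray(v, dtype=float)
        samples[ch] = v
        times[ch] = 60.0 * start_min + np.arange(v.size) / hz
    return SensorSegment(
        start_min=start_min, samples=samples, times=times,
        nominal_length=int(round(60 * hz)),
    )


@pytest.fixture
def tiny_cohort_config():
    """Small, fast cohort for pipeline-level tests."""
    return SimConfig(n_sessions=4, mean_duration_hr=1.0, sd_duration_hr=0.2, seed=11)
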