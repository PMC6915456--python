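"""Synthetic cohort generator.

The real study cohort (20 adults treated for acute vaso-occlusive pain, a
few hours of 1 Hz wrist-sensor data each, sparse app/nurse pain reports)
was never deposited, so every downstream stage is exercised on synthetic
sessions that reproduce its statistical structure:

* session durations ~ Normal(3.79 h, 2.23 h), truncated at 0.5 h;
* a latent pain trajectory p(t) that starts high (4-level category weights
  2/4/34/67 — the severe-skewed distribution of an acute-pain clinic) and
  decreases in expectation by ~2.75 points over the stay, piecewise
  constant with downward jumps at 2-4 simulated medication events;
* physiologic channels = baseline + coupling * p(t) + AR(1) noise, with
  higher pain raising heart rate and skin conductance by default;
* STEPS as a cumulative Poisson counter whose rate falls with pain
  (patients in pain move less);
* 2 app reports (kept to 2 decimals) and 3-4 nurse reports (rounded to
  integers) drawn from p(t) at random minutes.

A seed fully determines the cohort; sessions are seeded ``seed + index``.
Per-channel baselines and noise levels are plausible placeholders for a
wrist wearable, not estimates from any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import (
    ChannelName,
    PainRecord,
    PainSource,
    SensorStream,
    SessionBundle,
    ValidationError,
)

__all__ = ["SimConfig", "generate_session", "generate_cohort", "DEFAULT_BASELINES"]

#: Category bounds of the 4-level pain scale, used to draw starting scores.
_LEVEL_BOUNDS = ((0.0, 1.0), (1.0, 4.0), (4.0, 7.0), (7.0, 10.0))
#: Matched-sample counts per level observed in an acute-pain day hospital.
_LEVEL_WEIGHTS = (2.0, 4.0, 34.0, 67.0)

DEFAULT_BASELINES: Dict[ChannelName, float] = {
    ChannelName.HR: 85.0,     # beats/min, resting adult under stress
    ChannelName.RR: 0.75,     # s (~80 bpm equivalent)
    ChannelName.GSR: 200.0,   # kΩ skin resistance
    ChannelName.TEMP: 33.0,   # °C wrist skin temperature
    ChannelName.ACC_Z: 0.0,   # g, at rest
    ChannelName.GYR_Y: 0.0,   # deg/s
    ChannelName.GYR_Z: 0.0,   # deg/s
}

DEFAULT_NOISE_SD: Dict[ChannelName, float] = {
    ChannelName.HR: 3.0,
    ChannelName.RR: 0.04,
    ChannelName.GSR: 8.0,
    ChannelName.TEMP: 0.2,
    ChannelName.ACC_Z: 0.05,
    ChannelName.GYR_Y: 4.0,
    ChannelName.GYR_Z: 4.0,
}

#: Pain-effect coefficients, channel units per pain point.  STEPS is the
#: step *rate* effect in steps/s per pain point (applied before the
#: cumulative counter is formed).
DEFAULT_COUPLING: Dict[ChannelName, float] = {
    ChannelName.HR: 2.0,
    ChannelName.GSR: 5.0,
    ChannelName.STEPS: -0.02,
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters; ``seed`` fully determines output."""

    n_sessions: int = 20
    mean_duration_hr: float = 3.79
    sd_duration_hr: float = 2.23
    min_duration_hr: float = 0.5
    sampling_hz: float = 1.0
    level_weights: Tuple[float, float, float, float] = _LEVEL_WEIGHTS
    mean_pain_decrease: float = 2.75
    sd_pain_decrease: float = 2.34
    n_med_events: Tuple[int, int] = (2, 4)
    coupling: Dict[ChannelName, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    baselines: Dict[ChannelName, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    noise_sd: Dict[ChannelName, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    ar_coef: float = 0.9
    steps_base_rate: float = 0.25  # wrist-sensed steps/s at zero pain
    n_app_scores: int = 2
    n_nurse_scores: Tuple[int, int] = (3, 4)
    nurse_bias: float = 0.0  # additive shift on nurse-reported scores
    report_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 0:
            raise ValidationError("n_sessions must be non-negative")
        if self.mean_duration_hr <= 0 or self.min_duration_hr <= 0:
            raise ValidationError("durations must be positive")
        if self.sampling_hz <= 0:
            raise ValidationError("sampling_hz must be positive")
        if self.ar_coef < 0 or self.ar_coef >= 1:
            raise ValidationError("ar_coef must lie in [0, 1)")


def _draw_start_pain(rng: np.random.Generator, weights) -> float:
    w = np.asarray(weights, dtype=float)
    level = rng.choice(4, p=w / w.sum())
    lo, hi = _LEVEL_BOUNDS[level]
    return float(rng.uniform(lo, hi))


def _latent_trajectory(cfg: SimConfig, rng: np.random.Generator, n_sec: int) -> np.ndarray:
    """Piecewise-constant p(t) per second: downward jumps at medication times.

    The 4-level weights describe the distribution of *reported* scores
    (reports fall at random times during a decreasing stay), so the
    starting pain is the weighted draw shifted up by the expected
    decrease already incurred at a uniformly random report time
    (mean_pain_decrease / 2), capped at 10.
    """
    p0 = min(10.0, _draw_start_pain(rng, cfg.level_weights) + 0.5 * cfg.mean_pain_decrease)
    total_drop = float(np.clip(rng.normal(cfg.mean_pain_decrease, cfg.sd_pain_decrease), 0.0, p0))
    lo, hi = cfg.n_med_events
    n_events = int(rng.integers(lo, hi + 1))
    event_t = np.sort(rng.uniform(0, n_sec, size=n_events)).astype(int)
    drops = rng.dirichlet(np.ones(n_events)) * total_drop
    p = np.full(n_sec, p0, dtype=float)
    level = p0
    for t_ev, d in zip(event_t, drops):
        level = max(0.0, level - d)
        p[t_ev:] = level
    return p


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    white = rng.normal(0.0, innov_sd, size=n)
    white[0] = rng.normal(0.0, sd)  # start in stationarity
    return lfilter([1.0], [1.0, -phi], white)


def generate_session(
    config: SimConfig,
    session_index: int,
    return_truth: bool = False,
) -> Union[SessionBundle, Tuple[SessionBundle, pd.DataFrame]]:
    """Generate one synthetic session (deterministic in ``seed + index``).

    With ``return_truth=True`` also returns the latent per-minute pain
    trajectory as a DataFrame (columns ``minute``, ``pain``) for
    parameter-recovery tests; the analysis pipeline never reads it.
    """
    rng = np.random.default_rng(config.seed + session_index)
    duration_hr = float(rng.normal(config.mean_duration_hr, config.sd_duration_hr))
    while duration_hr < config.min_duration_hr:
        duration_hr = float(rng.normal(config.mean_duration_hr, config.sd_duration_hr))
    n_samples = int(round(duration_hr * 3600.0 * config.sampling_hz))
    t = np.arange(n_samples) / config.sampling_hz
    n_sec = int(np.ceil(t[-1])) + 1 if n_samples else 0

    p_sec = _latent_trajectory(config, rng, n_sec)
    p_at_samples = p_sec[np.floor(t).astype(int)] if n_samples else np.empty(0)

    streams: Dict[ChannelName, SensorStream] = {}
    for ch in ChannelName:
        if ch is ChannelName.STEPS:
            rate = config.steps_base_rate + config.coupling.get(ch, 0.0) * p_at_samples
            lam = np.clip(rate, 0.0, None) / config.sampling_hz
            increments = rng.poisson(lam) if np.any(lam > 0) else np.zeros(n_samples)
            values = np.cumsum(increments).astype(float)
        else:
            base = config.baselines.get(ch, 0.0)
            coup = config.coupling.get(ch, 0.0)
            noise = _ar1(rng, n_samples, config.noise_sd.get(ch, 0.0), config.ar_coef)
            values = base + coup * p_at_samples + noise
            if ch is ChannelName.RR:
                values = np.clip(values, 0.2, 2.0)  # physiological bounds
            elif ch is ChannelName.GSR:
                values = np.clip(values, 1.0, None)
        streams[ch] = SensorStream(channel=ch, timestamps=t.copy(), values=values)

    n_minutes = max(1, int(np.ceil(n_sec / 60.0))) if n_sec else 0
    pain: List[PainRecord] = []
    lo, hi = config.n_nurse_scores
    n_nurse = int(rng.integers(lo, hi + 1))
    for source, n_scores in ((PainSource.APP, config.n_app_scores), (PainSource.NURSE, n_nurse)):
        n_scores = min(n_scores, n_minutes)
        minutes = rng.choice(n_minutes, size=n_scores, replace=False)
        for m in np.sort(minutes):
            latent = p_sec[min(int(m) * 60, n_sec - 1)]
            score = latent + rng.normal(0.0, config.report_noise_sd) if config.report_noise_sd else latent
            if source is PainSource.NURSE:
                score = round(score + config.nurse_bias)
            else:
                score = round(score, 2)
            score = float(np.clip(score, 0.0, 10.0))
            pain.append(PainRecord(time_min=int(m), score=score, source=source))

    bundle = SessionBundle(session_id=f"S{session_index:03d}", streams=streams, pain=pain)
    if return_truth:
        minutes = np.arange(n_minutes)
        truth = pd.DataFrame(
            {"minute": minutes, "pain": p_sec[np.minimum(minutes * 60, n_sec - 1)]}
        )
        return bundle, truth
    return bundle


def generate_cohort(
    config: SimConfig, return_truth: bool = False
) -> Union[List[SessionBundle], Tuple[List[SessionBundle], List[pd.DataFrame]]]:
    """Generate ``config.n_sessions`` sessions, seeded ``seed + index``."""
    if not return_truth:
        return [generate_session(config, i) for i in range(config.n_sessions)]
    bundles, truths = [], []
    for i in range(config.n_sessions):
        b, tr = generate_session(config, i, return_truth=True)
        bundles.append(b)
        truths.append(tr)
    return bundles, truths
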