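"""Denoising and per-channel statistical features for 1-minute segments.

Each qualifying channel of a matched segment is passed through a centered
moving-average filter and summarised by eight statistics — mean, standard
deviation, mean derivative, RMS, peak-to-peak, peak-to-RMS, number of
peaks, and power — giving up to 64 named features per matched record.

Conventions (the source signals leave several choices open):

* the moving average is centered with edge truncation (window shrinks at
  the boundaries), default window 5 samples;
* standard deviation is the population form (1/n), consistent with the
  1/n used by RMS and power;
* the mean derivative is the mean of successive differences divided by
  the sampling interval, so its units are channel-units per second;
* a peak is an interior run of equal values strictly greater than both
  neighbours (a plateau counts once; endpoints never count);
* STEPS, a cumulative counter, is first-differenced to per-sample
  increments before filtering and statistics (on the raw counter most
  statistics degenerate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set

import numpy as np

from .types import (
    ChannelName,
    FeatureVector,
    SensorSegment,
    StatisticName,
    ValidationError,
    feature_name,
)

__all__ = [
    "FilterConfig",
    "StatisticError",
    "moving_average",
    "compute_statistic",
    "extract_features",
]


class StatisticError(ValueError):
    """A statistic's precondition failed (too-short or degenerate input)."""


@dataclass(frozen=True)
class FilterConfig:
    """Centered moving-average filter; window must be odd so the window is
    symmetric around each sample."""

    window: int = 5
    steps_as_increments: bool = True

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValidationError(f"window must be an odd positive integer, got {self.window}")


def moving_average(x: Sequence[float], cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Centered moving average with edge truncation.

    Output length equals input length; element i is the mean of the
    samples within the window centered at i, clipped to the sequence.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("moving_average requires a non-empty 1-d sequence")
    if cfg.window == 1 or arr.size == 1:
        return arr.copy()
    half = cfg.window // 2
    n = arr.size
    # direct per-window means: segments are short, and this avoids the
    # cancellation error of a cumulative-sum formulation
    return np.array(
        [arr[max(0, i - half): min(n, i + half + 1)].mean() for i in range(n)]
    )


# --- statistics -----------------------------------------------------------

_MIN_LENGTH = {
    StatisticName.STD: 2,
    StatisticName.MEAN_DERIVATIVE: 2,
    StatisticName.N_PEAKS: 2,
}


def _n_peaks(x: np.ndarray) -> int:
    """Interior runs of equal values strictly greater than both neighbours."""
    # compress to runs
    change = np.flatnonzero(np.diff(x) != 0)
    run_vals = x[np.concatenate(([0], change + 1))]
    if run_vals.size < 3:
        return 0
    interior = run_vals[1:-1]
    return int(np.sum((interior > run_vals[:-2]) & (interior > run_vals[2:])))


def compute_statistic(
    stat: StatisticName, x: Sequence[float], dt: float = 1.0
) -> float:
    """Evaluate one segment statistic on a sample sequence.

    ``dt`` is the sampling interval in seconds, used only by the mean
    derivative (units: channel-units/s).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("input must be 1-d")
    if arr.size < _MIN_LENGTH.get(stat, 1):
        raise StatisticError(
            f"{stat.value} requires at least {_MIN_LENGTH.get(stat, 1)} samples, got {arr.size}"
        )
    if stat is StatisticName.MEAN:
        return float(np.mean(arr))
    if stat is StatisticName.STD:
        return float(np.std(arr))  # population (1/n)
    if stat is StatisticName.MEAN_DERIVATIVE:
        if dt <= 0:
            raise ValidationError("dt must be positive")
        return float(np.mean(np.diff(arr)) / dt)
    if stat is StatisticName.RMS:
        return float(np.sqrt(np.mean(arr * arr)))
    if stat is StatisticName.PEAK_TO_PEAK:
        return float(np.max(arr) - np.min(arr))
    if stat is StatisticName.PEAK_TO_RMS:
        rms = np.sqrt(np.mean(arr * arr))
        if rms == 0.0:
            raise StatisticError("peak_to_rms undefined for an all-zero signal")
        return float(np.max(np.abs(arr)) / rms)
    if stat is StatisticName.N_PEAKS:
        return float(_n_peaks(arr))
    if stat is StatisticName.POWER:
        return float(np.mean(np.abs(arr) ** 2))
    raise ValueError(f"unknown statistic {stat!r}")


def extract_features(
    segment: SensorSegment, fcfg: FilterConfig = FilterConfig()
) -> FeatureVector:
    """Extract all statistics for every channel present in a segment.

    Pipeline per channel: difference STEPS to increments (if configured),
    moving-average filter, then the eight statistics on the filtered
    signal.  A channel/statistic pair whose precondition fails is flagged
    missing, never silently zeroed.  The result is deterministic and
    independent of channel iteration order.
    """
    values: Dict[str, float] = {}
    missing: Set[str] = set()
    for ch in ChannelName:
        if ch not in segment.samples:
            continue
        x = segment.samples[ch]
        t = segment.times[ch]
        if ch is ChannelName.STEPS and fcfg.steps_as_increments:
            x = np.diff(x)
            t = t[1:]
        if t.size > 1:
            dt = float((t[-1] - t[0]) / (t.size - 1))
        else:
            dt = 1.0
        if x.size == 0:
            missing.update(feature_name(ch, s) for s in StatisticName)
            continue
        filtered = moving_average(x, cfg=fcfg)
        for stat in StatisticName:
            key = feature_name(ch, stat)
            try:
                values[key] = compute_statistic(stat, filtered, dt=dt)
            except StatisticError:
                missing.add(key)
    return FeatureVector(values=values, missing=frozenset(missing))
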