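"""Domain data model for wearable-sensor pain-score estimation.

The study setting is an adult day hospital treating acute sickle-cell
vaso-occlusive pain.  Each monitored session consists of eight wrist-worn
sensor channels sampled nominally once per second, plus sparse subjective
pain reports (0-10 visual analog scale) entered either by the patient in a
mobile app (fractional scores allowed) or by nursing staff (typically
integers), timestamped at one-minute resolution.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ChannelName",
    "StatisticName",
    "PainSource",
    "PainCategory",
    "SensorStream",
    "PainRecord",
    "SessionBundle",
    "SensorSegment",
    "MatchedRecord",
    "FeatureVector",
    "ValidationError",
    "feature_name",
    "FEATURE_NAME_ORDER",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented domain invariant."""


class ChannelName(str, enum.Enum):
    """The eight wearable channels used for pain estimation.

    Units: HR beats/min, RR seconds, GSR kΩ, TEMP °C, ACC_Z g,
    GYR_Y / GYR_Z deg/s, STEPS cumulative step count.
    """

    HR = "HR"
    RR = "RR"
    GSR = "GSR"
    TEMP = "TEMP"
    ACC_Z = "ACC_Z"
    GYR_Y = "GYR_Y"
    GYR_Z = "GYR_Z"
    STEPS = "STEPS"

    @classmethod
    def parse(cls, name: str) -> "ChannelName":
        try:
            return cls(name)
        except ValueError:
            raise ValidationError(
                f"unknown channel name {name!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


#: Canonical channel ordering used for feature-table columns.
CHANNEL_ORDER: tuple = tuple(ChannelName)


class StatisticName(str, enum.Enum):
    """Per-channel segment statistics, in canonical order."""

    MEAN = "mean"
    STD = "std"
    MEAN_DERIVATIVE = "mean_derivative"
    RMS = "rms"
    PEAK_TO_PEAK = "peak_to_peak"
    PEAK_TO_RMS = "peak_to_rms"
    N_PEAKS = "n_peaks"
    POWER = "power"


STATISTIC_ORDER: tuple = tuple(StatisticName)


def feature_name(channel: ChannelName, stat: StatisticName) -> str:
    """Canonical ``<channel>__<statistic>`` feature identifier."""
    return f"{channel.value}__{stat.value}"


#: All 64 feature names in deterministic (channel-major) order.
FEATURE_NAME_ORDER: tuple = tuple(
    feature_name(c, s) for c in CHANNEL_ORDER for s in STATISTIC_ORDER
)


class PainSource(str, enum.Enum):
    APP = "app"
    NURSE = "nurse"

    @classmethod
    def parse(cls, name: str) -> "PainSource":
        try:
            return cls(name)
        except ValueError:
            raise ValidationError(
                f"unknown pain-score source {name!r}; expected 'app' or 'nurse'"
            ) from None


class PainCategory(enum.IntEnum):
    """Ordinal 4-level pain scale: none (0), mild (1-3), moderate (4-6),
    severe (7-10)."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class SensorStream:
    """One channel's timestamped samples for one session.

    Timestamps are seconds since session start, strictly increasing.
    STEPS is a cumulative counter and must be non-decreasing.
    """

    channel: ChannelName
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        vs = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vs)
        if ts.ndim != 1 or vs.ndim != 1 or ts.shape != vs.shape:
            raise ValidationError(
                f"{self.channel.value}: timestamps and values must be equal-length 1-d arrays"
            )
        if ts.size and ts[0] < 0:
            raise ValidationError(f"{self.channel.value}: negative timestamp {ts[0]}")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            i = int(np.argmax(np.diff(ts) <= 0))
            raise ValidationError(
                f"{self.channel.value}: timestamps not strictly increasing at index {i + 1} "
                f"(t={ts[i]} followed by t={ts[i + 1]})"
            )
        if self.channel is ChannelName.STEPS and vs.size > 1 and np.any(np.diff(vs) < 0):
            raise ValidationError("STEPS counter must be non-decreasing")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensorStream):
            return NotImplemented
        return (
            self.channel is other.channel
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True, order=True)
class PainRecord:
    """One subjective pain report: whole minutes since session start,
    score on the 0-10 visual analog scale, and who reported it."""

    time_min: int
    score: float
    source: PainSource

    def __post_init__(self) -> None:
        if self.time_min < 0 or int(self.time_min) != self.time_min:
            raise ValidationError(f"time_min must be a non-negative integer, got {self.time_min}")
        object.__setattr__(self, "time_min", int(self.time_min))
        object.__setattr__(self, "score", float(self.score))
        if not (0.0 <= self.score <= 10.0) or not math.isfinite(self.score):
            raise ValidationError(f"pain score {self.score} outside [0, 10]")


@dataclass
class SessionBundle:
    """All data for one monitored session: per-channel streams plus the
    ordered pain reports.  Channels may be missing (downstream stages
    operate on the available subset)."""

    session_id: str
    streams: Dict[ChannelName, SensorStream] = field(default_factory=dict)
    pain: List[PainRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ch, stream in self.streams.items():
            if stream.channel is not ch:
                raise ValidationError(
                    f"stream keyed {ch.value} carries channel {stream.channel.value}"
                )
        self.pain = sorted(self.pain, key=lambda p: (p.time_min, p.source.value, p.score))

    @property
    def duration_sec(self) -> float:
        """Span of the latest sensor sample, 0.0 if no streams."""
        ends = [s.timestamps[-1] for s in self.streams.values() if len(s)]
        return float(max(ends)) if ends else 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionBundle):
            return NotImplemented
        return (
            self.session_id == other.session_id
            and self.streams == other.streams
            and self.pain == other.pain
        )


@dataclass
class SensorSegment:
    """A 1-minute window of sensor data: samples (and their timestamps)
    per channel within [start_min, start_min + 1) minutes."""

    start_min: int
    samples: Dict[ChannelName, np.ndarray]
    times: Dict[ChannelName, np.ndarray]
    nominal_length: int

    def __post_init__(self) -> None:
        lo, hi = 60.0 * self.start_min, 60.0 * (self.start_min + 1)
        for ch, t in self.times.items():
            if t.size and (t[0] < lo or t[-1] >= hi):
                raise ValidationError(
                    f"{ch.value}: sample timestamps fall outside minute {self.start_min}"
                )

    @property
    def n_points(self) -> int:
        """Total sample count across channels in this window."""
        return int(sum(v.size for v in self.samples.values()))


@dataclass
class MatchedRecord:
    """A pain report paired with its 1-minute sensor segment.

    ``lag_min`` is the absolute whole-minute gap between the report and
    the segment start; 0 when an exact-minute segment existed.
    """

    pain: PainRecord
    segment: SensorSegment
    lag_min: int
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.lag_min != abs(self.pain.time_min - self.segment.start_min):
            raise ValidationError("lag_min inconsistent with pain/segment times")


@dataclass
class FeatureVector:
    """Named segment statistics (up to 64 = 8 channels x 8 statistics).

    ``values`` holds entries only for channel/statistic pairs that could be
    computed; pairs whose statistic precondition failed are listed in
    ``missing`` rather than silently zeroed.
    """

    values: Dict[str, float]
    missing: frozenset = frozenset()

    def __post_init__(self) -> None:
        bad = [k for k in self.values if k not in FEATURE_NAME_ORDER]
        bad += [k for k in self.missing if k not in FEATURE_NAME_ORDER]
        if bad:
            raise ValidationError(f"unknown feature names: {bad}")
        if set(self.values) & set(self.missing):
            raise ValidationError("a feature cannot be both present and missing")
        self.missing = frozenset(self.missing)

    @property
    def names(self) -> List[str]:
        """Feature names present, in canonical channel-major order."""
        return [n for n in FEATURE_NAME_ORDER if n in self.values]

    def __len__(self) -> int:
        return len(self.values)
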