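"""Segmenting sensor streams into 1-minute windows and matching pain reports.

Subjective pain reports carry minute-resolution timestamps while the
sensors stream at ~1 Hz, so each report is paired with the 1-minute sensor
segment recorded at the same minute; when no exact-minute segment exists,
the nearest segment within a tolerance (10 minutes by default, the
within-10-minutes rule) is used, on the assumption that pain changes
slowly over a few minutes.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .types import (
    ChannelName,
    MatchedRecord,
    PainRecord,
    SensorSegment,
    SessionBundle,
    ValidationError,
)

__all__ = ["MatchConfig", "segment_streams", "match_pain_to_segments", "match_session"]


@dataclass(frozen=True)
class MatchConfig:
    """Alignment parameters.

    tolerance_min: largest admissible |report minute - segment minute|.
    min_coverage: fraction of the nominal per-channel sample count
        (sampling_hz x 60) a channel must reach within a minute to be
        included in that minute's segment.
    strategy: "nearest" picks the closest admissible segment (ties toward
        the earlier one); "earliest" picks the earliest admissible segment.
    """

    tolerance_min: int = 10
    min_coverage: float = 0.8
    sampling_hz: float = 1.0
    strategy: str = "nearest"

    def __post_init__(self) -> None:
        if self.tolerance_min < 0:
            raise ValidationError("tolerance_min must be >= 0")
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValidationError("min_coverage must lie in (0, 1]")
        if self.strategy not in ("nearest", "earliest"):
            raise ValidationError("strategy must be 'nearest' or 'earliest'")

    @property
    def nominal_length(self) -> int:
        return int(round(self.sampling_hz * 60.0))


def segment_streams(bundle: SessionBundle, cfg: MatchConfig = MatchConfig()) -> List[SensorSegment]:
    """Cut a session into 1-minute segments.

    A channel enters a segment only if it has at least
    ``min_coverage * nominal_length`` samples within that minute; minutes
    where no channel qualifies are dropped.
    """
    if not bundle.streams:
        return []
    n_minutes = int(np.floor(bundle.duration_sec / 60.0)) + 1
    required = cfg.min_coverage * cfg.nominal_length

    per_minute: Dict[int, Tuple[Dict[ChannelName, np.ndarray], Dict[ChannelName, np.ndarray]]] = {}
    for ch, stream in bundle.streams.items():
        minute_of = np.floor(stream.timestamps / 60.0).astype(int)
        # streams are time-sorted, so each minute is one contiguous slice
        uniq, starts = np.unique(minute_of, return_index=True)
        bounds = np.append(starts, len(minute_of))
        for m, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
            if hi - lo >= required:
                samples, times = per_minute.setdefault(int(m), ({}, {}))
                samples[ch] = stream.values[lo:hi]
                times[ch] = stream.timestamps[lo:hi]

    segments = []
    for m in sorted(per_minute):
        samples, times = per_minute[m]
        segments.append(
            SensorSegment(start_min=m, samples=samples, times=times, nominal_length=cfg.nominal_length)
        )
    return segments


def match_pain_to_segments(
    pain: List[PainRecord],
    segments: List[SensorSegment],
    cfg: MatchConfig = MatchConfig(),
    session_id: str = "",
) -> Tuple[List[MatchedRecord], List[PainRecord]]:
    """Pair each pain report with at most one segment.

    Exact-minute segments always win (lag 0).  Otherwise the admissible
    segment chosen by ``cfg.strategy`` is used, with equidistant ties
    broken toward the earlier segment (physiology preceding the report).
    Reports with no segment within tolerance are returned unmatched;
    distinct reports may share one segment.
    """
    starts = [s.start_min for s in segments]
    if starts != sorted(starts):
        raise ValidationError("segments must be sorted by start_min")
    by_start = {s.start_min: s for s in segments}

    matched: List[MatchedRecord] = []
    unmatched: List[PainRecord] = []
    for rec in pain:
        seg = by_start.get(rec.time_min)
        if seg is None and starts:
            if cfg.strategy == "nearest":
                i = bisect.bisect_left(starts, rec.time_min)
                best = None
                for j in (i - 1, i):  # earlier candidate first -> wins ties
                    if 0 <= j < len(starts):
                        lag = abs(rec.time_min - starts[j])
                        if lag <= cfg.tolerance_min and (best is None or lag < best[0]):
                            best = (lag, j)
                seg = segments[best[1]] if best else None
            else:  # earliest admissible
                i = bisect.bisect_left(starts, rec.time_min - cfg.tolerance_min)
                if i < len(starts) and abs(starts[i] - rec.time_min) <= cfg.tolerance_min:
                    seg = segments[i]
        if seg is None:
            unmatched.append(rec)
        else:
            matched.append(
                MatchedRecord(
                    pain=rec,
                    segment=seg,
                    lag_min=abs(rec.time_min - seg.start_min),
                    session_id=session_id,
                )
            )
    return matched, unmatched


def match_session(
    bundle: SessionBundle, cfg: MatchConfig = MatchConfig()
) -> Tuple[List[MatchedRecord], List[PainRecord]]:
    """Segment one session and match its own pain reports (never across
    sessions)."""
    segments = segment_streams(bundle, cfg)
    return match_pain_to_segments(bundle.pain, segments, cfg, session_id=bundle.session_id)
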