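"""CSV readers and writers for the three on-disk dialects.

All files are UTF-8 comma-separated with "." decimal point:

* sensor CSV:  ``session_id,channel,t_sec,value``
* pain CSV:    ``session_id,t_min,score,source``
* feature CSV: ``session_id,t_min,<channel>__<statistic>...,score,source``

Timestamps are relative (seconds / minutes since session start); conversion
from wall clock happens at ingest, with the session's first sensor sample as
the origin.  Parsing never silently drops rows: in the default ``strict``
mode any malformed row raises, and in ``collect`` mode every row is counted
as either accepted or rejected in the returned :class:`ParseReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import (
    FEATURE_NAME_ORDER,
    ChannelName,
    FeatureVector,
    PainRecord,
    PainSource,
    SensorStream,
    SessionBundle,
    ValidationError,
)

__all__ = [
    "ParseError",
    "ParseReport",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_pain_csv",
    "write_pain_csv",
    "read_feature_table",
    "write_feature_table",
    "feature_table_frame",
    "SENSOR_HEADER",
    "PAIN_HEADER",
]

SENSOR_HEADER = ["session_id", "channel", "t_sec", "value"]
PAIN_HEADER = ["session_id", "t_min", "score", "source"]


class ParseError(ValueError):
    """A row (or the header) of an input CSV could not be parsed."""


@dataclass
class ParseReport:
    """Row accounting for a parse: accepted + rejected = total rows read."""

    n_rows: int = 0
    n_accepted: int = 0
    rejected: List[Tuple[int, str]] = field(default_factory=list)  # (row index, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _check_header(df: pd.DataFrame, expected: Sequence[str], path: Union[str, Path]) -> None:
    if list(df.columns) != list(expected):
        raise ParseError(
            f"{path}: header {list(df.columns)} does not match expected {list(expected)}"
        )


def read_sensor_csv(
    path: Union[str, Path],
    errors: str = "strict",
) -> Union[Dict[str, SessionBundle], Tuple[Dict[str, SessionBundle], ParseReport]]:
    """Read a sensor CSV into one :class:`SessionBundle` per session id.

    Rows are grouped by (session, channel) and sorted by timestamp; within
    a channel the sorted timestamps must be strictly increasing (duplicate
    timestamps are a validation error).  With ``errors="strict"`` (default)
    the first bad row raises :class:`ParseError`; with ``errors="collect"``
    bad rows are counted per-row in a :class:`ParseReport` and the report is
    returned alongside the bundles.
    """
    if errors not in ("strict", "collect"):
        raise ValueError("errors must be 'strict' or 'collect'")
    df = pd.read_csv(path, dtype={"session_id": str, "channel": str}, float_precision="round_trip")
    _check_header(df, SENSOR_HEADER, path)
    report = ParseReport(n_rows=len(df))

    keep = np.ones(len(df), dtype=bool)
    for i, (ch, t, v) in enumerate(zip(df["channel"], df["t_sec"], df["value"])):
        reason = None
        if ch not in ChannelName._value2member_map_:
            reason = f"row {i + 2}: unknown channel name {ch!r}"
        elif not np.isfinite(t) or t < 0:
            reason = f"row {i + 2}: bad timestamp {t!r}"
        elif not np.isfinite(v):
            reason = f"row {i + 2}: non-numeric value {v!r}"
        if reason is not None:
            if errors == "strict":
                raise ParseError(f"{path}: {reason}")
            report.rejected.append((i, reason))
            keep[i] = False
    df = df[keep]
    report.n_accepted = int(keep.sum())

    bundles: Dict[str, SessionBundle] = {}
    for sid, sgroup in df.groupby("session_id", sort=True):
        streams: Dict[ChannelName, SensorStream] = {}
        for ch_name, cgroup in sgroup.groupby("channel", sort=False):
            ch = ChannelName(ch_name)
            cgroup = cgroup.sort_values("t_sec", kind="stable")
            streams[ch] = SensorStream(
                channel=ch,
                timestamps=cgroup["t_sec"].to_numpy(dtype=float),
                values=cgroup["value"].to_numpy(dtype=float),
            )
        bundles[str(sid)] = SessionBundle(session_id=str(sid), streams=streams)
    if errors == "collect":
        return bundles, report
    return bundles


def write_sensor_csv(bundles: Iterable[SessionBundle], path: Union[str, Path]) -> None:
    """Write sensor streams in the sensor dialect, channels in canonical order."""
    rows = []
    for b in bundles:
        for ch in ChannelName:
            stream = b.streams.get(ch)
            if stream is None:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "session_id": b.session_id,
                        "channel": ch.value,
                        "t_sec": stream.timestamps,
                        "value": stream.values,
                    }
                )
            )
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=SENSOR_HEADER)
    )
    out.to_csv(path, index=False)


def read_pain_csv(
    path: Union[str, Path],
    errors: str = "strict",
) -> Union[Dict[str, List[PainRecord]], Tuple[Dict[str, List[PainRecord]], ParseReport]]:
    """Read a pain CSV into per-session lists of :class:`PainRecord`.

    Records are sorted by time; scores outside [0, 10] and unknown sources
    are rejected (raised in strict mode, counted in collect mode).
    """
    if errors not in ("strict", "collect"):
        raise ValueError("errors must be 'strict' or 'collect'")
    df = pd.read_csv(path, dtype={"session_id": str, "source": str}, float_precision="round_trip")
    _check_header(df, PAIN_HEADER, path)
    report = ParseReport(n_rows=len(df))

    per_session: Dict[str, List[PainRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            source = PainSource.parse(row.source)
            rec = PainRecord(time_min=int(row.t_min), score=float(row.score), source=source)
            if row.t_min != int(row.t_min):
                raise ValidationError(f"t_min {row.t_min} is not a whole minute")
        except (ValidationError, ValueError) as exc:
            reason = f"row {i + 2}: {exc}"
            if errors == "strict":
                raise ParseError(f"{path}: {reason}") from None
            report.rejected.append((i, reason))
            continue
        report.n_accepted += 1
        per_session.setdefault(str(row.session_id), []).append(rec)
    for sid in per_session:
        per_session[sid].sort(key=lambda p: (p.time_min, p.source.value, p.score))
    if errors == "collect":
        return per_session, report
    return per_session


def write_pain_csv(
    pain: Dict[str, List[PainRecord]], path: Union[str, Path]
) -> None:
    rows = [
        {"session_id": sid, "t_min": p.time_min, "score": p.score, "source": p.source.value}
        for sid in sorted(pain)
        for p in pain[sid]
    ]
    pd.DataFrame(rows, columns=PAIN_HEADER).to_csv(path, index=False)


FeatureEntry = Tuple[str, PainRecord, FeatureVector]


def feature_table_frame(entries: Sequence[FeatureEntry]) -> pd.DataFrame:
    """Assemble matched records into a wide feature table.

    One row per (session, pain report); feature columns in deterministic
    channel-major order.  All entries must share one feature-name set
    (union of present and missing); statistics flagged missing become NaN.
    """
    name_sets = {frozenset(set(fv.values) | set(fv.missing)) for _, _, fv in entries}
    if len(name_sets) > 1:
        raise ValidationError(
            "heterogeneous feature sets across records; "
            f"saw {sorted(len(s) for s in name_sets)} distinct sizes/sets"
        )
    names = [n for n in FEATURE_NAME_ORDER if name_sets and n in next(iter(name_sets))]
    rows = []
    for sid, pain, fv in entries:
        row = {"session_id": sid, "t_min": pain.time_min}
        for n in names:
            row[n] = fv.values.get(n, np.nan)
        row["score"] = pain.score
        row["source"] = pain.source.value
        rows.append(row)
    cols = ["session_id", "t_min", *names, "score", "source"]
    return pd.DataFrame(rows, columns=cols)


def write_feature_table(entries: Sequence[FeatureEntry], path: Union[str, Path]) -> None:
    feature_table_frame(entries).to_csv(path, index=False)


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"session_id": str, "source": str}, float_precision="round_trip")
    fixed_front, fixed_back = ["session_id", "t_min"], ["score", "source"]
    if list(df.columns[:2]) != fixed_front or list(df.columns[-2:]) != fixed_back:
        raise ParseError(f"{path}: not a feature-table CSV (fixed columns missing)")
    unknown = [c for c in df.columns[2:-2] if c not in FEATURE_NAME_ORDER]
    if unknown:
        raise ParseError(f"{path}: unknown feature columns {unknown}")
    return df
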