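"""Readers and writers for the pipeline's tabular interchange formats.

Canonical interchange is CSV (schemas documented in FORMATS.md): raw
tri-axial streams (``timestamp,x,y,z``), per-night sleep tables, and
the cohort summary tables.  Timestamps are ISO-8601 and timezone-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "read_raw_csv",
    "write_raw_csv",
    "write_sleep_table",
    "read_sleep_table",
]

MAX_ABS_G = 16.0
MAX_SPAN_DAYS = 9.0

SLEEP_TABLE_COLUMNS = [
    "participant_id", "night_index", "date", "dow",
    "onset_min", "wake_min", "duration_min", "qc_flags",
]


@dataclass
class RawRecording:
    """One participant's raw tri-axial acceleration stream.

    ``t`` holds seconds since ``start_time`` (strictly increasing),
    ``xyz`` the three axis arrays in gravitational units, shape (3, n).
    """

    participant_id: str
    start_time: pd.Timestamp
    t: np.ndarray
    xyz: np.ndarray
    nominal_rate: float
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.xyz = np.asarray(self.xyz)
        if self.xyz.shape != (3, self.t.size):
            raise ValueError("xyz must have shape (3, len(t))")
        if self.start_time.tzinfo is None:
            raise ValueError("start_time must be timezone-aware")
        if not self._validate:
            return
        if self.t.size and np.any(np.diff(self.t) <= 0):
            bad = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise ValueError(f"timestamps not strictly increasing at sample {bad}")
        if self.t.size and self.t[-1] - self.t[0] > MAX_SPAN_DAYS * 86400:
            raise ValueError(f"recording spans more than {MAX_SPAN_DAYS} days")
        if self.t.size and float(np.max(np.abs(self.xyz))) >= MAX_ABS_G:
            raise ValueError(f"axis values must satisfy |a| < {MAX_ABS_G} g")

    def __len__(self) -> int:
        return self.t.size

    @property
    def span_seconds(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


def read_raw_csv(path, participant_id: str, tz: str = "Europe/London") -> RawRecording:
    """Read a ``timestamp,x,y,z`` file into a validated :class:`RawRecording`.

    Naive timestamps are localized to ``tz``.  Malformed rows raise with
    the offending line number; an empty file raises a distinct error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if list(df.columns) != ["timestamp", "x", "y", "z"]:
        raise ValueError(f"{path}: header must be 'timestamp,x,y,z', got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: file has a header but no samples")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        ts = pd.to_datetime(df["timestamp"], errors="coerce")
        bad = int(np.argmax(ts.isna().to_numpy()))
        raise ValueError(f"{path}: malformed timestamp at line {bad + 2}: "
                         f"{df['timestamp'].iloc[bad]!r}") from exc
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(tz)
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.argmax(vals.isna().to_numpy()))
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad + 2}")
        df[col] = vals
    start = ts.iloc[0]
    t = (ts - start).dt.total_seconds().to_numpy()
    dup = np.flatnonzero(np.diff(t) <= 0)
    if dup.size:
        raise ValueError(f"{path}: duplicated or out-of-order timestamp at line {int(dup[0]) + 3}")
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 0.0
    xyz = np.vstack([df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy()])
    return RawRecording(participant_id=participant_id, start_time=start,
                        t=t, xyz=xyz, nominal_rate=rate)


def write_raw_csv(rec: RawRecording, path) -> None:
    """Write a recording back to the ``timestamp,x,y,z`` interchange form."""
    ts = rec.start_time + pd.to_timedelta(rec.t, unit="s")
    pd.DataFrame({
        "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
        "x": rec.xyz[0], "y": rec.xyz[1], "z": rec.xyz[2],
    }).to_csv(path, index=False)


def write_sleep_table(records: pd.DataFrame, path) -> None:
    """Write the per-night sleep table (one row per participant-night).

    An empty cohort yields a header-only file.  Written files are
    accepted losslessly by :func:`read_sleep_table`.
    """
    df = pd.DataFrame(records, columns=SLEEP_TABLE_COLUMNS) if len(records) == 0 \
        else records.loc[:, SLEEP_TABLE_COLUMNS]
    df = df.copy()
    df["qc_flags"] = df["qc_flags"].fillna("") if len(df) else df["qc_flags"]
    df.to_csv(path, index=False)


def read_sleep_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "qc_flags": str},
                     float_precision="round_trip")
    missing = set(SLEEP_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sleep table missing columns {sorted(missing)}")
    df["qc_flags"] = df["qc_flags"].fillna("")
    return df
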