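"""Reading and writing Empatica-E4-style session folders.

An E4 export is a folder of per-channel CSV files.  Value channels
(``EDA.csv``, ``TEMP.csv``, ``BVP.csv``) start with one header row holding
the epoch start time, one row holding the sampling rate in Hz, then one
sample per row.  ``ACC.csv`` has the same layout with three columns and
stores integer counts of 1/64 g.  ``IBI.csv`` starts with the epoch start
time and then rows of ``offset_seconds, interval_seconds`` — one row per
detected heartbeat, the interval being the time since the previous beat.

Internally all timestamps are epoch seconds and all inter-beat intervals
are milliseconds.  Interval slicing uses the half-open convention
``[t0, t1)`` throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SampledChannel",
    "BeatSeries",
    "Session",
    "STRESS_LABELS",
    "ParseError",
    "ValidationError",
    "read_e4_folder",
    "write_session",
    "slice_session",
    "read_label_table",
    "write_label_table",
]

#: closed set of stress levels used as class labels
STRESS_LABELS = ("relax", "mild", "high")

#: raw accelerometer unit: counts of 1/64 g
ACC_COUNTS_PER_G = 64.0

_VALUE_FILES = {"EDA": 4.0, "TEMP": 4.0, "BVP": 64.0}  # nominal rates, Hz


class ParseError(ValueError):
    """A channel file did not follow the expected CSV dialect."""


class ValidationError(ValueError):
    """A parsed object violated a structural invariant."""


@dataclass
class SampledChannel:
    """A uniformly sampled channel in physical units (µS, °C, or g)."""

    name: str
    start_time: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"channel {self.name}: fs must be > 0, got {self.fs}")
        if self.values.ndim != 1:
            raise ValidationError(f"channel {self.name}: values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"channel {self.name}: values must be finite")

    @property
    def duration(self) -> float:
        """Channel duration in seconds."""
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Epoch time of each sample."""
        return self.start_time + np.arange(len(self.values)) / self.fs


@dataclass
class BeatSeries:
    """Heartbeat event times with their preceding inter-beat intervals.

    ``ibis[i]`` is the interval (ms) ending at ``beat_times[i]``; beat times
    are offsets in seconds from ``start_time``.  ``artifact_mask[i]`` marks
    ``ibis[i]`` as a suspected artifact.
    """

    start_time: float
    beat_times: np.ndarray
    ibis: np.ndarray
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.ibis), dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.beat_times) != len(self.ibis):
            raise ValidationError("beat_times and ibis must have equal length")
        if len(self.artifact_mask) != len(self.ibis):
            raise ValidationError("artifact_mask must align with ibis")
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValidationError("beat_times must be strictly increasing")
        if np.any(self.ibis <= 0):
            raise ValidationError("all inter-beat intervals must be positive")

    def __len__(self) -> int:
        return len(self.ibis)

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1]) if len(self) else 0.0


@dataclass
class Session:
    """One synchronized multimodal recording block."""

    id: str
    channels: dict[str, SampledChannel] = field(default_factory=dict)
    beats: BeatSeries | None = None
    label: str | None = None
    tags: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in STRESS_LABELS:
            raise ValidationError(
                f"label must be one of {STRESS_LABELS}, got {self.label!r}"
            )

    @property
    def start_time(self) -> float:
        starts = [c.start_time for c in self.channels.values()]
        if self.beats is not None:
            starts.append(self.beats.start_time)
        if not starts:
            raise ValidationError("session has no channels or beats")
        return min(starts)

    @property
    def end_time(self) -> float:
        ends = [c.start_time + c.duration for c in self.channels.values()]
        if self.beats is not None and len(self.beats):
            ends.append(self.beats.start_time + self.beats.beat_times[-1])
        if not ends:
            raise ValidationError("session has no channels or beats")
        return max(ends)

    def acc(self) -> tuple[SampledChannel, SampledChannel, SampledChannel] | None:
        names = ("ACC_X", "ACC_Y", "ACC_Z")
        if all(n in self.channels for n in names):
            return tuple(self.channels[n] for n in names)  # type: ignore[return-value]
        return None


def _read_header_float(line: str, path: str, lineno: int) -> float:
    tok = line.strip().split(",")[0]
    try:
        return float(tok)
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: expected a number, got {line!r}") from exc


def _read_value_file(path: str, name: str) -> SampledChannel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: line 1: missing header rows")
    start = _read_header_float(lines[0], path, 1)
    fs = _read_header_float(lines[1], path, 2)
    try:
        values = np.array([float(v) for v in lines[2:] if v.strip()], dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed sample row") from exc
    return SampledChannel(name=name, start_time=start, fs=fs, values=values)


def _read_acc_file(path: str) -> list[SampledChannel]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: line 1: missing header rows")
    start = _read_header_float(lines[0], path, 1)
    fs = _read_header_float(lines[1], path, 2)
    rows = []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ParseError(f"{path}: line {i}: expected 3 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: malformed sample row") from exc
    arr = np.asarray(rows, dtype=float) / ACC_COUNTS_PER_G  # counts -> g
    return [
        SampledChannel(name=f"ACC_{ax}", start_time=start, fs=fs, values=arr[:, j])
        for j, ax in enumerate("XYZ")
    ]


def _read_ibi_file(path: str) -> BeatSeries:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: line 1: empty IBI file")
    start = _read_header_float(lines[0], path, 1)
    offsets, intervals = [], []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {i}: expected offset,interval")
        try:
            offsets.append(float(parts[0]))
            intervals.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: malformed IBI row") from exc
    offsets_a = np.asarray(offsets)
    if len(offsets_a) > 1 and not np.all(np.diff(offsets_a) > 0):
        raise ValidationError(f"{path}: IBI offsets must be strictly increasing")
    return BeatSeries(
        start_time=start,
        beat_times=offsets_a,
        ibis=np.asarray(intervals) * 1000.0,  # s -> ms
    )


def read_e4_folder(path: str, session_id: str | None = None) -> Session:
    """Read one E4-style session folder into a :class:`Session`.

    Missing channel files are allowed; at least one recognized file must be
    present.  ACC counts are converted to g and IBI intervals to ms.
    """
    session_id = session_id or os.path.basename(os.path.normpath(path))
    channels: dict[str, SampledChannel] = {}
    beats = None
    for name in _VALUE_FILES:
        fp = os.path.join(path, f"{name}.csv")
        if os.path.exists(fp):
            channels[name] = _read_value_file(fp, name)
    fp = os.path.join(path, "ACC.csv")
    if os.path.exists(fp):
        for ch in _read_acc_file(fp):
            channels[ch.name] = ch
    fp = os.path.join(path, "IBI.csv")
    if os.path.exists(fp):
        beats = _read_ibi_file(fp)
    if not channels and beats is None:
        raise ParseError(f"{path}: no recognized channel files found")
    label = None
    fp = os.path.join(path, "label.csv")
    if os.path.exists(fp):
        table = read_label_table(fp)
        row = table[table["session_id"] == session_id]
        if len(row):
            label = str(row["label"].iloc[0])
    return Session(id=session_id, channels=channels, beats=beats, label=label)


def write_session(session: Session, path: str) -> None:
    """Write a session as an E4-style folder readable by :func:`read_e4_folder`.

    Lossless to 6 decimals on every channel.  The label, when present, goes
    to a ``label.csv`` sidecar table.
    """
    if not session.channels and session.beats is None:
        raise ValidationError("refusing to write a session with no channels")
    os.makedirs(path, exist_ok=True)
    for name in _VALUE_FILES:
        ch = session.channels.get(name)
        if ch is None:
            continue
        with open(os.path.join(path, f"{name}.csv"), "w") as fh:
            fh.write(f"{ch.start_time:.6f}\n{ch.fs:.6f}\n")
            fh.writelines(f"{v:.6f}\n" for v in ch.values)
    acc = session.acc()
    if acc is not None:
        x, y, z = acc
        with open(os.path.join(path, "ACC.csv"), "w") as fh:
            fh.write(f"{x.start_time:.6f},{x.start_time:.6f},{x.start_time:.6f}\n")
            fh.write(f"{x.fs:.6f},{x.fs:.6f},{x.fs:.6f}\n")
            counts = np.column_stack([x.values, y.values, z.values]) * ACC_COUNTS_PER_G
            fh.writelines(f"{a:.6f},{b:.6f},{c:.6f}\n" for a, b, c in counts)
    if session.beats is not None:
        b = session.beats
        with open(os.path.join(path, "IBI.csv"), "w") as fh:
            fh.write(f"{b.start_time:.6f}\n")
            fh.writelines(
                f"{t:.6f},{ibi / 1000.0:.6f}\n" for t, ibi in zip(b.beat_times, b.ibis)
            )
    if session.label is not None:
        table = pd.DataFrame(
            [
                {
                    "session_id": session.id,
                    "t_start": session.start_time,
                    "t_end": session.end_time,
                    "label": session.label,
                }
            ]
        )
        write_label_table(table, os.path.join(path, "label.csv"))


def read_label_table(path: str) -> pd.DataFrame:
    """Read a sidecar label table (session_id, t_start, t_end, label)."""
    table = pd.read_csv(path, dtype={"session_id": str})
    required = {"session_id", "t_start", "t_end", "label"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: label table missing columns {sorted(missing)}")
    bad = set(table["label"]) - set(STRESS_LABELS)
    if bad:
        raise ValidationError(f"{path}: unknown labels {sorted(bad)}")
    return table


def write_label_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def slice_session(session: Session, t0: float, t1: float) -> Session:
    """Restrict a session to the half-open epoch window ``[t0, t1)``.

    Channel and beat start times are adjusted so the sliced session lives on
    the same epoch clock.  Raises :class:`ValidationError` when the window
    does not intersect the recording.
    """
    if not t0 < t1:
        raise ValidationError(f"need t0 < t1, got [{t0}, {t1})")
    if t1 <= session.start_time or t0 >= session.end_time:
        raise ValidationError("slice window does not intersect the recording")
    channels: dict[str, SampledChannel] = {}
    for name, ch in session.channels.items():
        # first sample index with time >= t0; half-open cut at t1
        i0 = max(0, int(np.ceil((t0 - ch.start_time) * ch.fs - 1e-9)))
        i1 = min(len(ch.values), int(np.ceil((t1 - ch.start_time) * ch.fs - 1e-9)))
        if i1 <= i0:
            continue
        channels[name] = replace(
            ch, start_time=ch.start_time + i0 / ch.fs, values=ch.values[i0:i1]
        )
    beats = None
    if session.beats is not None and len(session.beats):
        b = session.beats
        abs_times = b.start_time + b.beat_times
        keep = (abs_times >= t0) & (abs_times < t1)
        if keep.any():
            beats = BeatSeries(
                start_time=t0,
                beat_times=abs_times[keep] - t0,
                ibis=b.ibis[keep],
                artifact_mask=b.artifact_mask[keep],
            )
    if not channels and beats is None:
        raise ValidationError("slice window contains no samples")
    return Session(
        id=session.id, channels=channels, beats=beats, label=session.label,
        tags=session.tags,
    )
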