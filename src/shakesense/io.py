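"""File-backed I/O for IMU recordings, annotation events and session manifests.

Recordings are comma-delimited UTF-8 text with one header row and a time
column in seconds (``t,ax,ay,az[,gx,gy,gz]``).  Acceleration is expressed in
units of standard gravity (g), so a stationary sensor has an acceleration
norm of ~1.  Annotation files are CSV (``label,start_s,end_s,error_flag``)
with times relative to the recording's first sample.  A session manifest is a
JSON document tying recordings and annotations to participants, tasks and
sensor positions.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorPosition",
    "ImuRecording",
    "AnnotationEvent",
    "SessionEntry",
    "Session",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "load_session",
    "save_session",
    "DEFAULT_FS",
]

DEFAULT_FS = 100.0
#: absolute tolerance on timestamp uniformity, in seconds
TIME_TOL = 1e-9

ANNOTATION_LABELS = ("aggressive", "light", "daily_care")


class FormatError(ValueError):
    """Raised when a sensor, annotation or manifest file violates its format."""


class SensorPosition(str, Enum):
    """One of the six body sites a sensor is attached to."""

    HEAD = "head"
    CHEST = "chest"
    LEFT_ARM = "left_arm"
    RIGHT_ARM = "right_arm"
    LEFT_LEG = "left_leg"
    RIGHT_LEG = "right_leg"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_channel(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise FormatError(f"channel {name!r} must be one-dimensional")
    return arr


@dataclass
class ImuRecording:
    """One sensor's multichannel time series for one task.

    Acceleration channels ``ax, ay, az`` are in g; optional angular-velocity
    channels ``gx, gy, gz`` are in deg/s.  Sample times ``t`` are in seconds,
    strictly increasing with constant step ``1/fs``.
    """

    recording_id: str
    position: SensorPosition
    fs: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: Optional[np.ndarray] = None
    gy: Optional[np.ndarray] = None
    gz: Optional[np.ndarray] = None
    participant_id: str = ""
    task_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.position = SensorPosition(self.position)
        if not self.fs > 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        if self.task_id is not None and not 1 <= int(self.task_id) <= 18:
            raise FormatError(f"task_id must be in 1..18, got {self.task_id}")
        self.t = _as_channel(self.t, "t")
        self.ax = _as_channel(self.ax, "ax")
        self.ay = _as_channel(self.ay, "ay")
        self.az = _as_channel(self.az, "az")
        n = len(self.t)
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise FormatError(
                    f"channel {name!r} has length {len(getattr(self, name))}, expected {n}"
                )
        gyro = [self.gx, self.gy, self.gz]
        if any(g is not None for g in gyro):
            if any(g is None for g in gyro):
                raise FormatError("gyroscope channels must be all present or all absent")
            self.gx = _as_channel(self.gx, "gx")
            self.gy = _as_channel(self.gy, "gy")
            self.gz = _as_channel(self.gz, "gz")
            for name in ("gx", "gy", "gz"):
                if len(getattr(self, name)) != n:
                    raise FormatError(f"channel {name!r} has length mismatch")
        if n >= 2:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                i = int(np.argmax(steps <= 0))
                raise FormatError(f"timestamps not strictly increasing at row {i + 1}")
            if np.any(np.abs(steps - 1.0 / self.fs) > TIME_TOL):
                i = int(np.argmax(np.abs(steps - 1.0 / self.fs) > TIME_TOL))
                raise FormatError(
                    f"non-uniform timestamp step at row {i + 1}: "
                    f"{steps[i]!r} != 1/fs = {1.0 / self.fs!r}"
                )

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def has_gyro(self) -> bool:
        return self.gx is not None

    def accel(self) -> np.ndarray:
        """The (3, n) stacked acceleration channels, in g."""
        return np.vstack([self.ax, self.ay, self.az])

    def with_accel(self, acc: np.ndarray) -> "ImuRecording":
        """A copy of this recording with replaced acceleration channels."""
        acc = np.asarray(acc, dtype=float)
        if acc.shape != (3, self.n):
            raise FormatError(f"expected shape (3, {self.n}), got {acc.shape}")
        return replace(self, ax=acc[0].copy(), ay=acc[1].copy(), az=acc[2].copy())


@dataclass(frozen=True)
class AnnotationEvent:
    """A labeled time interval used as ground truth for window labeling.

    ``error_flag`` marks an event voided by an operator error; flagged events
    are retained on read but must be excluded from labeling.
    """

    label: str
    start_s: float
    end_s: float
    error_flag: bool = False

    def __post_init__(self) -> None:
        if self.label not in ANNOTATION_LABELS:
            raise FormatError(
                f"unknown annotation label {self.label!r}; expected one of {ANNOTATION_LABELS}"
            )
        if self.start_s < 0:
            raise FormatError(f"start_s must be >= 0, got {self.start_s}")
        if not self.end_s > self.start_s:
            raise FormatError(
                f"end_s ({self.end_s}) must be greater than start_s ({self.start_s})"
            )


@dataclass
class SessionEntry:
    """One manifest row: a recording, its annotations and its metadata."""

    recording: ImuRecording
    events: list[AnnotationEvent]
    participant_id: str
    task_id: int
    position: SensorPosition

    def __post_init__(self) -> None:
        self.position = SensorPosition(self.position)


@dataclass
class Session:
    """A complete data-collection run: every (participant, task, position) recording."""

    session_id: str
    entries: list[SessionEntry] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.participant_id, e.task_id, e.position)
            if key in seen:
                raise FormatError(f"duplicate (participant, task, position) triple: {key}")
            seen.add(key)

    @property
    def n_recordings(self) -> int:
        return len(self.entries)

    def tasks(self) -> list[tuple[str, int]]:
        """Distinct (participant_id, task_id) pairs, in entry order."""
        out: list[tuple[str, int]] = []
        seen = set()
        for e in self.entries:
            key = (e.participant_id, e.task_id)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def task_label_counts(self) -> dict[str, int]:
        """Task-level bookkeeping: total tasks and aggressive vs non-aggressive."""
        labels: dict[tuple[str, int], str] = {}
        for e in self.entries:
            key = (e.participant_id, e.task_id)
            lab = next((ev.label for ev in e.events if not ev.error_flag), None)
            if key not in labels and lab is not None:
                labels[key] = lab
        n_aggressive = sum(1 for v in labels.values() if v == "aggressive")
        return {
            "n_tasks": len(self.tasks()),
            "n_aggressive": n_aggressive,
            "n_non_aggressive": len(labels) - n_aggressive,
        }

    def by_position(self) -> dict[SensorPosition, list[SessionEntry]]:
        out: dict[SensorPosition, list[SessionEntry]] = {}
        for e in self.entries:
            out.setdefault(e.position, []).append(e)
        return out


# ---------------------------------------------------------------------------
# recordings

_REQUIRED_COLUMNS = ("t", "ax", "ay", "az")
_GYRO_COLUMNS = ("gx", "gy", "gz")
# %.17g round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def read_recording(
    path: str | Path,
    position: SensorPosition,
    fs: float = DEFAULT_FS,
    recording_id: Optional[str] = None,
    participant_id: str = "",
    task_id: Optional[int] = None,
) -> ImuRecording:
    """Read a delimited-text recording and validate it.

    The file must have a header row naming at least ``t, ax, ay, az``;
    gyroscope columns ``gx, gy, gz`` are attached when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"recording {path} is missing required column {col!r}")
    gyro = {}
    if all(c in df.columns for c in _GYRO_COLUMNS):
        gyro = {c: df[c].to_numpy(dtype=float) for c in _GYRO_COLUMNS}
    return ImuRecording(
        recording_id=recording_id or path.stem,
        position=SensorPosition(position),
        fs=fs,
        t=df["t"].to_numpy(dtype=float),
        ax=df["ax"].to_numpy(dtype=float),
        ay=df["ay"].to_numpy(dtype=float),
        az=df["az"].to_numpy(dtype=float),
        participant_id=participant_id,
        task_id=task_id,
        **gyro,
    )


def write_recording(rec: ImuRecording, path: str | Path) -> Path:
    """Write a recording as CSV at full double precision (1e-9 round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [rec.t, rec.ax, rec.ay, rec.az]
    header = "t,ax,ay,az"
    if rec.has_gyro:
        cols += [rec.gx, rec.gy, rec.gz]
        header += ",gx,gy,gz"
    data = np.column_stack(cols) if rec.n > 0 else np.empty((0, len(cols)))
    np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter=",", header=header, comments="")
    return path


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> list[AnnotationEvent]:
    """Read annotation events; result is sorted by start time.

    Error-flagged events are retained (marked), so callers can report them;
    labeling must filter them out.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    for col in ("label", "start_s", "end_s", "error_flag"):
        if col not in df.columns:
            raise FormatError(f"annotation file {path} is missing column {col!r}")
    events = []
    for row in df.itertuples(index=False):
        flag = row.error_flag
        if isinstance(flag, str):
            flag = flag.strip().lower() in ("true", "1", "yes")
        events.append(
            AnnotationEvent(
                label=str(row.label),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                error_flag=bool(flag),
            )
        )
    return sorted(events, key=lambda e: (e.start_s, e.end_s))


def write_annotations(events: Sequence[AnnotationEvent], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label,start_s,end_s,error_flag\n")
        for e in events:
            fh.write(
                f"{e.label},{_FLOAT_FMT % e.start_s},{_FLOAT_FMT % e.end_s},"
                f"{'true' if e.error_flag else 'false'}\n"
            )
    return path


# ---------------------------------------------------------------------------
# manifests


def save_session(session: Session, out_dir: str | Path, fs: float = DEFAULT_FS) -> Path:
    """Write every recording and annotation file plus ``manifest.json``.

    Returns the manifest path.  Paths inside the manifest are relative to the
    manifest's directory so the session tree is relocatable.
    """
    out_dir = Path(out_dir)
    (out_dir / "recordings").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    entries = []
    for e in session.entries:
        rid = e.recording.recording_id
        rec_rel = f"recordings/{rid}.csv"
        ann_rel = f"annotations/{rid}.csv"
        write_recording(e.recording, out_dir / rec_rel)
        write_annotations(e.events, out_dir / ann_rel)
        entries.append(
            {
                "recording": rec_rel,
                "annotations": ann_rel,
                "participant_id": e.participant_id,
                "task_id": e.task_id,
                "position": e.position.value,
            }
        )
    manifest = {
        "session_id": session.session_id,
        "seed": session.seed,
        "fs": fs,
        "entries": entries,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


def load_session(manifest_path: str | Path) -> Session:
    """Load a session from a manifest (JSON object or bare JSON array of entries)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        doc = {"session_id": manifest_path.stem, "seed": None, "entries": doc}
    base = manifest_path.parent
    fs = float(doc.get("fs", DEFAULT_FS))
    entries = []
    for i, row in enumerate(doc["entries"]):
        rec_path = base / row["recording"]
        ann_path = base / row["annotations"]
        for p in (rec_path, ann_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest entry {i} ({row.get('participant_id')}, task "
                    f"{row.get('task_id')}, {row.get('position')}) references "
                    f"missing file: {p}"
                )
        rec = read_recording(
            rec_path,
            position=SensorPosition(row["position"]),
            fs=fs,
            participant_id=str(row["participant_id"]),
            task_id=int(row["task_id"]),
        )
        entries.append(
            SessionEntry(
                recording=rec,
                events=read_annotations(ann_path),
                participant_id=str(row["participant_id"]),
                task_id=int(row["task_id"]),
                position=SensorPosition(row["position"]),
            )
        )
    seed = doc.get("seed")
    return Session(
        session_id=str(doc.get("session_id", manifest_path.stem)),
        entries=entries,
        seed=None if seed is None else int(seed),
    )
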