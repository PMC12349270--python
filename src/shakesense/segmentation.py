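"""Sliding-window segmentation of the acceleration-norm series and
annotation-driven window labeling.

Recordings are split into fixed-length windows (default 3 s) where adjacent
windows share a fixed overlap (default 1 s, i.e. the window start advances by
2 s).  Only complete windows are emitted.  Each window's binary ground-truth
label is resolved from the annotation events by a maximum-overlap rule:
the event class covering the most samples wins, light movement and daily
care both map to non-aggressive, and a window with less than half its
samples inside any event is left unlabeled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import acceleration_norm
from .io import AnnotationEvent, ImuRecording, SensorPosition, Session

__all__ = [
    "Segment",
    "sliding_windows",
    "label_window",
    "segment_recording",
    "segment_session",
    "LABEL_AGGRESSIVE",
    "LABEL_NON_AGGRESSIVE",
    "LABEL_UNLABELED",
]

logger = logging.getLogger(__name__)

LABEL_AGGRESSIVE = "aggressive"
LABEL_NON_AGGRESSIVE = "non_aggressive"
LABEL_UNLABELED = "unlabeled"

DEFAULT_WINDOW_S = 3.0
DEFAULT_OVERLAP_S = 1.0
#: minimum fraction of a window's samples that must lie inside an event
MIN_COVERAGE = 0.5


@dataclass
class Segment:
    """One window of a recording's acceleration-norm series, with its label."""

    recording_id: str
    position: SensorPosition
    start_idx: int
    end_idx: int
    norm: np.ndarray
    label: str
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.position = SensorPosition(self.position)
        if self.label not in (LABEL_AGGRESSIVE, LABEL_NON_AGGRESSIVE, LABEL_UNLABELED):
            raise ValueError(f"unknown segment label {self.label!r}")
        self.norm = np.asarray(self.norm, dtype=float)
        if len(self.norm) != self.end_idx - self.start_idx:
            raise ValueError("norm length does not match window bounds")


def sliding_windows(
    n: int,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> list[tuple[int, int]]:
    """Half-open sample-index windows ``[start, end)`` covering ``n`` samples.

    Window starts advance by ``window_s - overlap_s``; only complete windows
    are emitted, so ``floor((n - w) / step) + 1`` windows for ``n >= w``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0 < overlap_s < window_s:
        raise ValueError(
            f"overlap_s must satisfy 0 < overlap_s < window_s (got {overlap_s}, {window_s})"
        )
    w = int(round(window_s * fs))
    step = int(round((window_s - overlap_s) * fs))
    if w <= 0 or step <= 0:
        raise ValueError("window and step must span at least one sample")
    if n < w:
        return []
    starts = range(0, n - w + 1, step)
    return [(s, s + w) for s in starts]


def label_window(
    window: tuple[int, int],
    events: Sequence[AnnotationEvent],
    fs: float,
    min_coverage: float = MIN_COVERAGE,
) -> str:
    """Resolve a window's binary label from annotation events.

    Sample ``i`` (at time ``i/fs``) belongs to an event when
    ``start_s <= i/fs < end_s``.  Error-flagged events are ignored.  The
    event class covering the most samples wins; ties go to non-aggressive;
    light and daily-care map to non-aggressive.
    """
    a, b = window
    w = b - a
    covered = np.zeros(w, dtype=bool)
    class_masks: dict[str, np.ndarray] = {}
    for ev in events:
        if ev.error_flag:
            continue
        # first/last sample indices inside [start_s, end_s)
        lo = max(a, int(np.ceil(ev.start_s * fs - 1e-9)))
        hi = min(b, int(np.ceil(ev.end_s * fs - 1e-9)))
        if hi <= lo:
            continue
        mask = class_masks.setdefault(ev.label, np.zeros(w, dtype=bool))
        mask[lo - a : hi - a] = True
        covered[lo - a : hi - a] = True
    if covered.sum() < min_coverage * w:
        return LABEL_UNLABELED
    counts = {label: int(m.sum()) for label, m in class_masks.items()}
    agg = counts.get("aggressive", 0)
    non_agg = max(
        (c for label, c in counts.items() if label != "aggressive"), default=0
    )
    return LABEL_AGGRESSIVE if agg > non_agg else LABEL_NON_AGGRESSIVE


def segment_recording(
    rec: ImuRecording,
    events: Sequence[AnnotationEvent],
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> list[Segment]:
    """All windows of one recording, each carrying its norm slice and label."""
    norm = acceleration_norm(rec.ax, rec.ay, rec.az)
    out = []
    for a, b in sliding_windows(rec.n, rec.fs, window_s, overlap_s):
        out.append(
            Segment(
                recording_id=rec.recording_id,
                position=rec.position,
                start_idx=a,
                end_idx=b,
                norm=norm[a:b],
                label=label_window((a, b), events, rec.fs),
                participant_id=rec.participant_id,
            )
        )
    return out


def segment_session(
    session: Session,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> dict[SensorPosition, list[Segment]]:
    """Segment every recording; labeled segments grouped by sensor position.

    Unlabeled windows are excluded from the returned modeling set; their
    count is reported in the log.
    """
    by_position: dict[SensorPosition, list[Segment]] = {}
    n_unlabeled = 0
    n_total = 0
    for entry in session.entries:
        segs = segment_recording(entry.recording, entry.events, window_s, overlap_s)
        n_total += len(segs)
        for seg in segs:
            if seg.label == LABEL_UNLABELED:
                n_unlabeled += 1
                continue
            by_position.setdefault(seg.position, []).append(seg)
    n_agg = sum(
        1 for segs in by_position.values() for s in segs if s.label == LABEL_AGGRESSIVE
    )
    logger.info(
        "segmented %d recordings: %d windows, %d labeled (%d aggressive), %d unlabeled",
        len(session.entries), n_total, n_total - n_unlabeled, n_agg, n_unlabeled,
    )
    return by_position
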