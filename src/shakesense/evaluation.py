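"""Confusion matrices, performance metrics and per-position reports.

The positive class is aggressive movement throughout: sensitivity is the
recall of aggressive segments, specificity the recall of non-aggressive
segments.  Metrics are stored at full precision; rounding (half-up to two
decimals) is applied only at the reporting layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .features import FEATURE_NAMES, feature_matrix
from .io import SensorPosition, Session
from .segmentation import Segment, segment_session
from .tree import DecisionTree, feature_importance, fit_tree, predict, split_data

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "EvalConfig",
    "PositionResult",
    "confusion",
    "compute_metrics",
    "evaluate_position",
    "evaluate_all_positions",
    "round_half_up",
]

METRIC_NAMES = ("accuracy", "precision", "specificity", "sensitivity")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to mirror how results tables are printed."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with aggressive as the positive class."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class Metrics:
    """The four headline ratios; undefined ratios are NaN with the metric
    name recorded in ``undefined`` (never silently zero)."""

    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {m: round_half_up(getattr(self, m), ndigits) for m in METRIC_NAMES}


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"y_true and y_pred lengths differ: {y_true.shape} vs {y_pred.shape}"
        )
    return ConfusionMatrix(
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
    )


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision, specificity and sensitivity from confusion counts."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    acc = (cm.tp + cm.tn) / cm.total
    prec = ratio(cm.tp, cm.tp + cm.fp, "precision")
    spec = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    sens = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    return Metrics(
        accuracy=acc,
        precision=prec,
        specificity=spec,
        sensitivity=sens,
        undefined=tuple(undefined),
    )


@dataclass
class EvalConfig:
    """Knobs of the train/evaluate stage."""

    seed: int = 0
    window_s: float = 3.0
    overlap_s: float = 1.0
    train_frac: float = 0.7
    split_mode: str = "segment"  # "segment" | "participant"
    max_depth: int = 2

    def validate(self) -> None:
        if not 0 < self.overlap_s < self.window_s:
            raise ValueError("overlap_s must satisfy 0 < overlap_s < window_s")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.split_mode not in ("segment", "participant"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class PositionResult:
    """One row of the per-position report."""

    position: SensorPosition
    absent: bool = False
    n_segments: int = 0
    n_train: int = 0
    n_test: int = 0
    cm: Optional[ConfusionMatrix] = None
    metrics: Optional[Metrics] = None
    importances: Optional[np.ndarray] = None
    importances_normalized: bool = False
    tree: Optional[DecisionTree] = None
    train_idx: Optional[np.ndarray] = None
    test_idx: Optional[np.ndarray] = None

    def top_feature(self) -> Optional[str]:
        if self.importances is None or not self.importances_normalized:
            return None
        return FEATURE_NAMES[int(np.argmax(self.importances))]


def _split_seed(base_seed: int, position: SensorPosition) -> np.random.SeedSequence:
    idx = list(SensorPosition).index(position)
    return np.random.SeedSequence([int(base_seed), 1, idx])


def fit_and_score(
    X: np.ndarray,
    y: np.ndarray,
    groups,
    position: SensorPosition,
    config: EvalConfig,
) -> PositionResult:
    """Split, fit one depth-capped tree and score it on the held-out rows.

    This is the shared core of the in-memory and file-driven pipelines; the
    split seed is derived deterministically from (config.seed, position).
    """
    config.validate()
    train_idx, test_idx = split_data(
        y,
        train_frac=config.train_frac,
        seed=_split_seed(config.seed, position),
        stratified=True,
        group_ids=groups,
    )
    tree = fit_tree(X[train_idx], y[train_idx], max_depth=config.max_depth)
    y_pred = predict(tree, X[test_idx])
    cm = confusion(y[test_idx], y_pred)
    imp, normalized = feature_importance(tree)
    return PositionResult(
        position=position,
        n_segments=len(y),
        n_train=len(train_idx),
        n_test=len(test_idx),
        cm=cm,
        metrics=compute_metrics(cm),
        importances=imp,
        importances_normalized=normalized,
        tree=tree,
        train_idx=train_idx,
        test_idx=test_idx,
    )


def evaluate_position(
    segments: Sequence[Segment],
    fs: float,
    position: SensorPosition,
    config: EvalConfig,
) -> PositionResult:
    """Featurize, split, fit one depth-capped tree and score it on the test set."""
    X, y = feature_matrix(segments, fs)
    groups = None
    if config.split_mode == "participant":
        groups = [s.participant_id for s in segments]
    return fit_and_score(X, y, groups, position, config)


def evaluate_all_positions(
    session: Session,
    config: EvalConfig,
    fs: Optional[float] = None,
) -> list[PositionResult]:
    """Train and evaluate one tree per sensor position.

    A position with no segments yields a row marked absent; the run
    continues for the remaining positions.
    """
    config.validate()
    if fs is None:
        fs = session.entries[0].recording.fs if session.entries else 100.0
    by_pos = segment_session(session, config.window_s, config.overlap_s)
    results = []
    for position in SensorPosition:
        segs = by_pos.get(position)
        if not segs:
            results.append(PositionResult(position=position, absent=True))
            continue
        results.append(evaluate_position(segs, fs, position, config))
    return results
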