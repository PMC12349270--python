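"""Configuration-driven orchestration: simulate -> segment -> featurize ->
train -> evaluate, with one seed funneled through every stage.

``run_pipeline`` executes the whole chain in memory and writes the feature
table, the six serialized models, the split indices and the evaluation
report (CSV with two-decimal metrics, JSON at full precision with a config
echo and hash).  Each stage is also exposed as a file-driven function so the
CLI subcommands compose through files to the identical result.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .evaluation import (
    EvalConfig,
    PositionResult,
    compute_metrics,
    confusion,
    fit_and_score,
)
from .features import FEATURE_NAMES, features_to_frame
from .io import SensorPosition, Session, load_session, save_session
from .segmentation import segment_session
from .synthetic import MotionParams, Protocol, default_protocol
from .tree import DecisionTree, feature_importance, predict

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "run_pipeline",
    "stage_segment",
    "stage_features",
    "stage_train",
    "stage_evaluate",
]

logger = logging.getLogger(__name__)

_CSV_FLOAT_FMT = "%.17g"


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; the seed is recorded in every output."""

    seed: int = 0
    window_s: float = 3.0
    overlap_s: float = 1.0
    train_frac: float = 0.7
    split_mode: str = "segment"  # "segment" | "participant"
    max_depth: int = 2
    motion: MotionParams = field(default_factory=MotionParams)
    protocol: Union[str, Protocol] = "default"
    manifest: Optional[str] = None  # user-supplied session instead of simulation
    output_dir: str = "shakesense_out"
    persist_data: bool = False  # also write simulated recordings + manifest

    def validate(self) -> None:
        self.eval_config().validate()
        self.motion.validate()
        if self.manifest is None:
            self.resolve_protocol()

    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            seed=self.seed,
            window_s=self.window_s,
            overlap_s=self.overlap_s,
            train_frac=self.train_frac,
            split_mode=self.split_mode,
            max_depth=self.max_depth,
        )

    def resolve_protocol(self) -> Protocol:
        if isinstance(self.protocol, Protocol):
            return self.protocol
        if self.protocol == "default":
            return default_protocol()
        raise ValueError(f"unknown protocol {self.protocol!r}")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        motion = dataclasses.asdict(self.motion)
        for key in ("attenuation_trunk", "attenuation_arms"):
            motion[key] = {p.value: v for p, v in getattr(self.motion, key).items()}
        if isinstance(self.protocol, Protocol):
            proto = {
                "n_participants": self.protocol.n_participants,
                "positions": [p.value for p in self.protocol.positions],
                "task_ids": [t.task_id for t in self.protocol.tasks],
            }
        else:
            proto = self.protocol
        return {
            "seed": self.seed,
            "window_s": self.window_s,
            "overlap_s": self.overlap_s,
            "train_frac": self.train_frac,
            "split_mode": self.split_mode,
            "max_depth": self.max_depth,
            "motion": motion,
            "protocol": proto,
            "manifest": self.manifest,
            "persist_data": self.persist_data,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        motion = doc.pop("motion", None)
        if isinstance(motion, dict):
            kwargs = dict(motion)
            for key in ("attenuation_trunk", "attenuation_arms"):
                if key in kwargs:
                    kwargs[key] = {
                        SensorPosition(p): float(v) for p, v in kwargs[key].items()
                    }
            for key, val in list(kwargs.items()):
                if isinstance(val, list):
                    kwargs[key] = tuple(val)
            motion = MotionParams(**kwargs)
        proto = doc.pop("protocol", "default")
        if isinstance(proto, dict):
            base = default_protocol()
            task_ids = proto.get("task_ids")
            tasks = [t for t in base.tasks if task_ids is None or t.task_id in task_ids]
            positions = [
                SensorPosition(p)
                for p in proto.get("positions", [q.value for q in SensorPosition])
            ]
            proto = Protocol(
                tasks=tasks,
                n_participants=int(proto.get("n_participants", base.n_participants)),
                positions=positions,
            )
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(doc) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        cfg = cls(**doc, **({"motion": motion} if motion is not None else {}),
                  protocol=proto)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)


@dataclass
class PipelineReport:
    results: list[PositionResult]
    report_csv: Path
    report_json: Path
    features_csv: Path
    models_dir: Path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def result_record(res: PositionResult) -> dict:
    """Full-precision JSON record for one position row."""
    if res.absent:
        return {"absent": True}
    return {
        "absent": False,
        "n_segments": res.n_segments,
        "n_train": res.n_train,
        "n_test": res.n_test,
        "confusion": {
            "tn": res.cm.tn, "fp": res.cm.fp, "fn": res.cm.fn, "tp": res.cm.tp,
        },
        "metrics": {
            m: getattr(res.metrics, m)
            for m in ("accuracy", "precision", "specificity", "sensitivity")
        },
        "metrics_rounded": res.metrics.rounded(),
        "undefined_metrics": list(res.metrics.undefined),
        "importances": {
            name: float(v) for name, v in zip(FEATURE_NAMES, res.importances)
        },
        "top_feature": res.top_feature(),
        "model": res.tree.to_dict(),
    }


def write_report(
    results: list[PositionResult], config: PipelineConfig, out_dir: Path
) -> tuple[Path, Path]:
    """Write report.csv (two-decimal metrics) and report.json (full precision)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "report.csv"
    lines = ["position,tn,fp,fn,tp,accuracy,precision,specificity,sensitivity"]
    for res in results:
        if res.absent:
            lines.append(f"{res.position.value},,,,,,,,")
            continue
        r = res.metrics.rounded()
        lines.append(
            f"{res.position.value},{res.cm.tn},{res.cm.fp},{res.cm.fn},{res.cm.tp},"
            f"{r['accuracy']:.2f},{r['precision']:.2f},"
            f"{r['specificity']:.2f},{r['sensitivity']:.2f}"
        )
    csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    json_path = out_dir / "report.json"
    doc = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "results": {res.position.value: result_record(res) for res in results},
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return csv_path, json_path


def frame_position_matrices(frame: pd.DataFrame, position: SensorPosition):
    """(X, y, groups) for one position's rows of a feature table, in row order."""
    sub = frame[frame["position"] == position.value]
    X = sub[FEATURE_NAMES].to_numpy(dtype=float)
    y = (sub["label"] == "aggressive").to_numpy(dtype=int)
    groups = sub["participant_id"].to_numpy()
    return X, y, groups


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage in order on simulated or user-supplied data.

    Idempotent for a fixed config and seed: two runs produce byte-identical
    feature tables, models and reports.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # stage: acquire session
    if config.manifest is not None:
        logger.info("loading session from %s", config.manifest)
        session = load_session(config.manifest)
    else:
        from .synthetic import simulate_session

        protocol = config.resolve_protocol()
        logger.info(
            "simulating session: %d participants x %d tasks x %d positions (seed %d)",
            protocol.n_participants, len(protocol.tasks), len(protocol.positions),
            config.seed,
        )
        session = simulate_session(
            protocol,
            config.motion,
            seed=config.seed,
            out_dir=(out_dir / "data") if config.persist_data else None,
        )
        counts = session.task_label_counts()
        logger.info(
            "simulated %d recordings (%d tasks: %d aggressive, %d non-aggressive)",
            session.n_recordings, counts["n_tasks"], counts["n_aggressive"],
            counts["n_non_aggressive"],
        )
    fs = session.entries[0].recording.fs if session.entries else 100.0

    # stage: segment + featurize
    by_pos = segment_session(session, config.window_s, config.overlap_s)
    all_segments = [s for pos in SensorPosition for s in by_pos.get(pos, [])]
    frame = features_to_frame(all_segments, fs)
    features_csv = out_dir / "features.csv"
    frame.to_csv(features_csv, index=False, float_format=_CSV_FLOAT_FMT)

    # stage: train + evaluate per position
    models_dir = out_dir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    eval_config = config.eval_config()
    results: list[PositionResult] = []
    splits: dict[str, dict] = {}
    for position in SensorPosition:
        X, y, groups = frame_position_matrices(frame, position)
        if len(y) == 0:
            results.append(PositionResult(position=position, absent=True))
            continue
        res = fit_and_score(
            X, y,
            groups if config.split_mode == "participant" else None,
            position, eval_config,
        )
        res.tree.save(models_dir / f"{position.value}.json")
        splits[position.value] = {
            "train_idx": res.train_idx.tolist(),
            "test_idx": res.test_idx.tolist(),
        }
        results.append(res)
        logger.info(
            "%s: n=%d train=%d test=%d metrics=%s",
            position.value, res.n_segments, res.n_train, res.n_test,
            res.metrics.rounded(),
        )
    with open(out_dir / "splits.json", "w", encoding="utf-8") as fh:
        json.dump({"seed": config.seed, "splits": splits}, fh, indent=2, sort_keys=True)
        fh.write("\n")

    report_csv, report_json = write_report(results, config, out_dir)
    return PipelineReport(
        results=results,
        report_csv=report_csv,
        report_json=report_json,
        features_csv=features_csv,
        models_dir=models_dir,
    )

# ---------------------------------------------------------------------------
# file-driven stages (CLI surface); chaining them reproduces run_pipeline


def stage_segment(
    manifest: str | Path,
    out_csv: str | Path,
    window_s: float = 3.0,
    overlap_s: float = 1.0,
) -> Path:
    """Segment a session on disk into a labeled-segment table (metadata only).

    Rows are ordered by sensor position then session entry order, matching
    the in-memory pipeline.
    """
    session = load_session(manifest)
    by_pos = segment_session(session, window_s, overlap_s)
    rows = []
    for pos in SensorPosition:
        for seg in by_pos.get(pos, []):
            rows.append(
                {
                    "recording_id": seg.recording_id,
                    "participant_id": seg.participant_id,
                    "position": seg.position.value,
                    "start_idx": seg.start_idx,
                    "end_idx": seg.end_idx,
                    "label": seg.label,
                }
            )
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame.from_records(
        rows,
        columns=["recording_id", "participant_id", "position", "start_idx",
                 "end_idx", "label"],
    ).to_csv(out_csv, index=False)
    return out_csv


def stage_features(
    manifest: str | Path,
    segments_csv: str | Path,
    out_csv: str | Path,
) -> Path:
    """Compute the feature table for a segment table, reloading norms from disk."""
    from .features import acceleration_norm
    from .segmentation import Segment

    session = load_session(manifest)
    norms = {
        e.recording.recording_id: acceleration_norm(
            e.recording.ax, e.recording.ay, e.recording.az
        )
        for e in session.entries
    }
    fs = session.entries[0].recording.fs if session.entries else 100.0
    seg_frame = pd.read_csv(Path(segments_csv))
    if len(seg_frame) == 0:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        features_to_frame([], fs).to_csv(out_csv, index=False, float_format=_CSV_FLOAT_FMT)
        return out_csv
    segments = []
    for row in seg_frame.itertuples(index=False):
        if row.recording_id not in norms:
            raise FileNotFoundError(
                f"segment references unknown recording {row.recording_id!r}"
            )
        segments.append(
            Segment(
                recording_id=row.recording_id,
                position=SensorPosition(row.position),
                start_idx=int(row.start_idx),
                end_idx=int(row.end_idx),
                norm=norms[row.recording_id][int(row.start_idx): int(row.end_idx)],
                label=row.label,
                participant_id=str(row.participant_id),
            )
        )
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    features_to_frame(segments, fs).to_csv(
        out_csv, index=False, float_format=_CSV_FLOAT_FMT
    )
    return out_csv


def stage_train(
    features_csv: str | Path,
    out_dir: str | Path,
    config: EvalConfig,
) -> Path:
    """Fit one tree per position from a feature table; write models + splits."""
    from .evaluation import _split_seed
    from .tree import fit_tree, split_data

    config.validate()
    frame = pd.read_csv(Path(features_csv), dtype={"participant_id": str}, float_precision="round_trip")
    out_dir = Path(out_dir)
    models_dir = out_dir / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    splits: dict[str, dict] = {}
    for position in SensorPosition:
        X, y, groups = frame_position_matrices(frame, position)
        if len(y) == 0:
            continue
        train_idx, test_idx = split_data(
            y,
            train_frac=config.train_frac,
            seed=_split_seed(config.seed, position),
            stratified=True,
            group_ids=groups if config.split_mode == "participant" else None,
        )
        tree = fit_tree(X[train_idx], y[train_idx], max_depth=config.max_depth)
        tree.save(models_dir / f"{position.value}.json")
        splits[position.value] = {
            "train_idx": train_idx.tolist(),
            "test_idx": test_idx.tolist(),
        }
    with open(out_dir / "splits.json", "w", encoding="utf-8") as fh:
        json.dump({"seed": config.seed, "splits": splits}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def stage_evaluate(
    features_csv: str | Path,
    models_dir: str | Path,
    splits_path: str | Path,
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> tuple[Path, Path]:
    """Score saved models on their held-out rows and write the report."""
    frame = pd.read_csv(Path(features_csv), dtype={"participant_id": str}, float_precision="round_trip")
    with open(splits_path, encoding="utf-8") as fh:
        splits = json.load(fh)["splits"]
    models_dir = Path(models_dir)
    if config is None:
        config = PipelineConfig()
    results: list[PositionResult] = []
    for position in SensorPosition:
        X, y, _groups = frame_position_matrices(frame, position)
        model_path = models_dir / f"{position.value}.json"
        if len(y) == 0 or not model_path.exists():
            results.append(PositionResult(position=position, absent=True))
            continue
        tree = DecisionTree.load(model_path)
        sp = splits[position.value]
        train_idx = np.asarray(sp["train_idx"], dtype=int)
        test_idx = np.asarray(sp["test_idx"], dtype=int)
        y_pred = predict(tree, X[test_idx])
        cm = confusion(y[test_idx], y_pred)
        imp, normalized = feature_importance(tree)
        results.append(
            PositionResult(
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
        )
    return write_report(results, config, Path(out_dir))
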