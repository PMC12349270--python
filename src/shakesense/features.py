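"""Acceleration-norm computation and per-segment feature extraction.

The per-sample acceleration norm (signal magnitude vector)
``sqrt(ax^2 + ay^2 + az^2)`` is orientation-invariant: rotating the sensor
axes leaves it unchanged.  Each window of the norm series is summarized by
11 descriptive statistics: mean, standard deviation, 10th/50th/95th
percentiles, minimum, maximum, skewness, kurtosis, root mean square, average
frequency and entropy.  The last two are spectral: the power-weighted mean
frequency (spectral centroid) and the Shannon entropy of the normalized
one-sided periodogram of the mean-removed norm, in bits.  Beyond mean
removal no filtering or detrending is applied.

Conventions for degenerate (zero-variance) windows: skewness and excess
kurtosis are defined as 0, and both spectral features are 0 (no oscillatory
power).
"""
from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "acceleration_norm",
    "extract_features",
    "feature_matrix",
    "features_to_frame",
]

FEATURE_NAMES = [
    "mean_g",
    "std_g",
    "p10_g",
    "p50_g",
    "p95_g",
    "min_g",
    "max_g",
    "skewness",
    "kurtosis",
    "rms_g",
    "avg_freq_hz",
    "entropy_bits",
]


@dataclass(frozen=True)
class FeatureVector:
    """The per-segment statistics of the acceleration norm.

    Percentile fields are in g (the 50th percentile is the median); skewness
    and kurtosis are dimensionless (kurtosis is excess: normal -> 0);
    ``avg_freq_hz`` is the spectral centroid and ``entropy_bits`` the
    spectral entropy of the mean-removed norm.
    """

    mean_g: float
    std_g: float
    p10_g: float
    p50_g: float
    p95_g: float
    min_g: float
    max_g: float
    skewness: float
    kurtosis: float
    rms_g: float
    avg_freq_hz: float
    entropy_bits: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"feature {f.name} is not finite: {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def acceleration_norm(ax, ay, az) -> np.ndarray:
    """Element-wise Euclidean magnitude ``sqrt(ax^2 + ay^2 + az^2)``, in g."""
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError(
            f"axis lengths differ: {ax.shape}, {ay.shape}, {az.shape}"
        )
    return np.sqrt(ax * ax + ay * ay + az * az)


def extract_features(norm: Sequence[float], fs: float) -> FeatureVector:
    """Compute all descriptive statistics of one window of the norm series.

    Standard deviation and the higher moments use the population convention
    (divide by n); percentiles interpolate linearly between order statistics.
    """
    x = np.asarray(norm, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("norm series must be one-dimensional with length >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    mean = float(x.mean())
    std = float(x.std())
    p10, p50, p95 = (float(v) for v in np.percentile(x, [10, 50, 95]))
    mn = float(x.min())
    mx = float(x.max())
    rms = float(np.sqrt(np.mean(x * x)))
    if std > 0:
        d = x - mean
        skew = float(np.mean(d**3) / std**3)
        kurt = float(np.mean(d**4) / std**4 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    freqs, power = sps.periodogram(x - mean, fs=fs)
    freqs, power = freqs[1:], power[1:]  # exclude DC
    total = float(power.sum())
    if total > 0:
        avg_freq = float(np.sum(freqs * power) / total)
        p = power / total
        p = p[p > 0]
        entropy = float(-np.sum(p * np.log2(p)))
    else:
        avg_freq = 0.0
        entropy = 0.0
    return FeatureVector(
        mean_g=mean,
        std_g=std,
        p10_g=p10,
        p50_g=p50,
        p95_g=p95,
        min_g=mn,
        max_g=mx,
        skewness=skew,
        kurtosis=kurt,
        rms_g=rms,
        avg_freq_hz=avg_freq,
        entropy_bits=entropy,
    )


def feature_matrix(segments: Sequence, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-segment feature vectors; labels are 1 = aggressive, 0 = not.

    Row order matches segment order.  Raises if any segment is unlabeled.
    """
    from .segmentation import LABEL_AGGRESSIVE, LABEL_UNLABELED

    rows = []
    labels = []
    for seg in segments:
        if seg.label == LABEL_UNLABELED:
            raise ValueError(
                f"segment {seg.recording_id}[{seg.start_idx}:{seg.end_idx}] is unlabeled"
            )
        rows.append(extract_features(seg.norm, fs).to_array())
        labels.append(1 if seg.label == LABEL_AGGRESSIVE else 0)
    if not rows:
        return np.empty((0, len(FEATURE_NAMES))), np.empty((0,), dtype=int)
    return np.vstack(rows), np.asarray(labels, dtype=int)


def features_to_frame(segments: Sequence, fs: float) -> pd.DataFrame:
    """Feature table with one row per segment, for CSV export."""
    records = []
    for seg in segments:
        fv = extract_features(seg.norm, fs)
        row = {name: getattr(fv, name) for name in FEATURE_NAMES}
        row.update(
            recording_id=seg.recording_id,
            participant_id=seg.participant_id,
            position=seg.position.value,
            start_idx=seg.start_idx,
            end_idx=seg.end_idx,
            label=seg.label,
        )
        records.append(row)
    cols = FEATURE_NAMES + [
        "recording_id", "participant_id", "position", "start_idx", "end_idx", "label",
    ]
    return pd.DataFrame.from_records(records, columns=cols)
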