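"""Windowed statistical featurization of 8-channel recordings.

Each (compressed) recording is cut into consecutive non-overlapping windows
of ``window_size`` samples (default 20; any trailing remainder is dropped)
and each window is summarized per channel by five statistics — mean, max,
min, variance, standard deviation — giving the 40-column feature table the
classifier consumes. 12,000 samples per gait with a 20-sample window thus
yield 600 rows per gait, 2400 rows over the four gaits.

Variance is the population variance (divide by n); std is its square root.
Columns are channel-major, ``<channel>.<stat>``, stats ordered
(mean, max, min, variance, std).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import CHANNEL_NAMES, MotionRecording

__all__ = [
    "STAT_NAMES",
    "FeatureMatrix",
    "MinMaxScaler",
    "window_stats",
    "featurize",
    "featurize_dataset",
    "scale_features",
]

STAT_NAMES: tuple[str, ...] = ("mean", "max", "min", "variance", "std")

FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{channel}.{stat}" for channel in CHANNEL_NAMES for stat in STAT_NAMES
)


@dataclass(frozen=True)
class FeatureMatrix:
    """A windows x 40 statistical feature table with per-row gait labels."""

    values: np.ndarray
    labels: np.ndarray
    window_size: int
    column_names: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 2 or values.shape[1] != len(self.column_names):
            raise ValueError(
                f"values must have {len(self.column_names)} columns"
            )
        if len(labels) != values.shape[0]:
            raise ValueError("one label per row required")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.column_names))
        df["label"] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, window_size: int) -> "FeatureMatrix":
        cols = [c for c in df.columns if c != "label"]
        return cls(
            values=df[cols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            window_size=window_size,
            column_names=tuple(cols),
        )

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        window_size = parts[0].window_size
        cols = parts[0].column_names
        if any(p.window_size != window_size or p.column_names != cols for p in parts):
            raise ValueError("incompatible feature matrices")
        return FeatureMatrix(
            values=np.vstack([p.values for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            window_size=window_size,
            column_names=cols,
        )


def window_stats(window: np.ndarray) -> tuple[float, float, float, float, float]:
    """Five summary statistics of one window: (mean, max, min, variance, std).

    Variance divides by n (population variance); std = sqrt(variance).
    """
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    var = float(w.var())
    return float(w.mean()), float(w.max()), float(w.min()), var, float(np.sqrt(var))


def featurize(
    values: np.ndarray, label: str, window_size: int = 20
) -> FeatureMatrix:
    """Featurize a frames x 8 matrix into non-overlapping window statistics.

    Frames are partitioned into consecutive windows of ``window_size``; the
    trailing remainder (fewer than ``window_size`` frames) is dropped.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(CHANNEL_NAMES):
        raise ValueError("expected a frames x 8 matrix")
    n_frames = values.shape[0]
    if n_frames < window_size:
        raise ValueError(
            f"recording shorter than window: {n_frames} < {window_size}"
        )
    n_windows = n_frames // window_size
    trimmed = values[: n_windows * window_size]
    # windows x window_size x channels
    cube = trimmed.reshape(n_windows, window_size, len(CHANNEL_NAMES))
    mean = cube.mean(axis=1)
    mx = cube.max(axis=1)
    mn = cube.min(axis=1)
    var = cube.var(axis=1)
    std = np.sqrt(var)
    # channel-major interleave: for each channel the 5 stats in order
    stacked = np.stack([mean, mx, mn, var, std], axis=2)  # windows x ch x 5
    feat = stacked.reshape(n_windows, len(CHANNEL_NAMES) * len(STAT_NAMES))
    labels = np.full(n_windows, label, dtype=object)
    return FeatureMatrix(values=feat, labels=labels, window_size=window_size)


def featurize_dataset(
    recordings: list[MotionRecording], window_size: int = 20
) -> FeatureMatrix:
    """Featurize and stack a list of recordings (labels carried per row)."""
    return FeatureMatrix.concat(
        [featurize(r.values, r.gait_label, window_size) for r in recordings]
    )


@dataclass(frozen=True)
class MinMaxScaler:
    """Column-wise min-max map fitted on training data only.

    Sigmoid decoders need reconstruction targets in [0, 1], so features are
    affinely mapped with the training minima/maxima; constant columns map
    to 0. Test columns may fall slightly outside [0, 1] — that is expected
    and harmless.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray) -> "MinMaxScaler":
        values = np.asarray(values, dtype=float)
        return cls(mins=values.min(axis=0), maxs=values.max(axis=0))

    def transform(self, values: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = (np.asarray(values, dtype=float) - self.mins) / safe
        return np.where(span > 0, out, 0.0)

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        return np.asarray(scaled, dtype=float) * (self.maxs - self.mins) + self.mins


def scale_features(
    train: FeatureMatrix, test: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix, MinMaxScaler]:
    """Min-max scale both splits to [0, 1] using training statistics only."""
    if train.column_names != test.column_names:
        raise ValueError("train and test must share columns")
    scaler = MinMaxScaler.fit(train.values)
    scaled_train = FeatureMatrix(
        scaler.transform(train.values), train.labels, train.window_size,
        train.column_names,
    )
    scaled_test = FeatureMatrix(
        scaler.transform(test.values), test.labels, test.window_size,
        test.column_names,
    )
    return scaled_train, scaled_test, scaler
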