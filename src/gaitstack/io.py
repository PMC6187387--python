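"""Delimited-text I/O for recordings and feature tables.

Recordings are CSV files with the 8 fixed channel names as header and one
frame per row; gait label, seed and frame count travel in a JSON sidecar
(``<name>.meta.json``). Feature tables are CSV with ``channel.stat`` columns
plus a ``label`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .features import FeatureMatrix
from .synth import CHANNEL_NAMES, MotionRecording

__all__ = [
    "save_recording",
    "load_recording",
    "save_features",
    "load_features",
]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_recording(recording: MotionRecording, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(recording.values, columns=list(CHANNEL_NAMES)).to_csv(
        path, index=False
    )
    _meta_path(path).write_text(
        json.dumps(
            {
                "gait_label": recording.gait_label,
                "seed": recording.seed,
                "n_frames": recording.n_frames,
            }
        )
    )


def load_recording(path: str | Path) -> MotionRecording:
    path = Path(path)
    df = pd.read_csv(path)
    if tuple(df.columns) != CHANNEL_NAMES:
        raise ValueError(
            f"recording {path} does not have the expected 8-channel header"
        )
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    return MotionRecording(
        values=df.to_numpy(dtype=float),
        gait_label=meta.get("gait_label", "walk"),
        seed=int(meta.get("seed", -1)),
    )


def save_features(features: FeatureMatrix, path: str | Path) -> None:
    features.to_frame().to_csv(Path(path), index=False)


def load_features(path: str | Path, window_size: int = 20) -> FeatureMatrix:
    df = pd.read_csv(Path(path))
    if "label" not in df.columns:
        raise ValueError(f"feature table {path} lacks a 'label' column")
    return FeatureMatrix.from_frame(df, window_size=window_size)
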