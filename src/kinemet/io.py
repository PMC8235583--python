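"""Delimited-text readers and writers.

Skeleton sequences, MET traces and feature matrices travel as UTF-8 CSV
with a mandatory header row and '.' decimal separator:

* skeleton: ``timestamp_s, <JOINT>_x, <JOINT>_y, <JOINT>_z, ...``
* MET trace: ``timestamp_s, met``
* features: ``timestamp_s, <JOINT>_vx, ...`` (or ``PC1..PCm``)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .sequence import SkeletonSequence
from .simulate import METTrace

__all__ = [
    "write_skeleton_csv",
    "read_skeleton_csv",
    "write_met_csv",
    "read_met_csv",
    "write_features_csv",
    "read_features_csv",
]

_AXES = ("x", "y", "z")


def write_skeleton_csv(sequence: SkeletonSequence, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {"timestamp_s": sequence.timestamps}
    for i, joint in enumerate(sequence.joint_names):
        for a, axis in enumerate(_AXES):
            cols[f"{joint}_{axis}"] = sequence.positions[:, i, a]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_skeleton_csv(
    path: str | Path,
    frame_rate: float | None = None,
    **metadata,
) -> SkeletonSequence:
    df = pd.read_csv(path)
    if "timestamp_s" not in df.columns:
        raise ValueError(f"{path}: skeleton CSV needs a timestamp_s column")
    joints: list[str] = []
    for col in df.columns:
        if col.endswith("_x") and col != "timestamp_s":
            joints.append(col[:-2])
    if not joints:
        raise ValueError(f"{path}: no <JOINT>_x/_y/_z columns found")
    for j in joints:
        for axis in _AXES:
            if f"{j}_{axis}" not in df.columns:
                raise ValueError(f"{path}: joint {j} lacks the _{axis} column")
    n = len(df)
    positions = np.empty((n, len(joints), 3))
    for i, j in enumerate(joints):
        for a, axis in enumerate(_AXES):
            positions[:, i, a] = df[f"{j}_{axis}"].to_numpy(float)
    ts = df["timestamp_s"].to_numpy(float)
    if frame_rate is None:
        dt = np.median(np.diff(ts)) if n > 1 else 1.0 / 30.0
        frame_rate = 1.0 / dt
    return SkeletonSequence(
        timestamps=ts,
        joint_names=tuple(joints),
        positions=positions,
        frame_rate=frame_rate,
        **metadata,
    )


def write_met_csv(trace: METTrace, path: str | Path) -> None:
    pd.DataFrame({"timestamp_s": trace.timestamps, "met": trace.met_values}).to_csv(
        path, index=False
    )


def read_met_csv(path: str | Path) -> METTrace:
    df = pd.read_csv(path)
    for col in ("timestamp_s", "met"):
        if col not in df.columns:
            raise ValueError(f"{path}: MET CSV needs a {col} column")
    return METTrace(
        timestamps=df["timestamp_s"].to_numpy(float), met_values=df["met"].to_numpy(float)
    )


def write_features_csv(features: FeatureMatrix, path: str | Path) -> None:
    features.to_dataframe().to_csv(path, index=False)


def read_features_csv(path: str | Path, **metadata) -> FeatureMatrix:
    df = pd.read_csv(path)
    ts = None
    if "timestamp_s" in df.columns:
        ts = df["timestamp_s"].to_numpy(float)
        df = df.drop(columns=["timestamp_s"])
    return FeatureMatrix(
        values=df.to_numpy(float), columns=tuple(df.columns), timestamps=ts, **metadata
    )
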