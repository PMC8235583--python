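"""Velocity features and the 90%-variance PCA reduction.

Treadmill gaits are close to left-right symmetric, so only the six
left-side joints (shoulder, elbow, wrist, hip, knee, ankle) are analysed.
Per-frame finite-difference velocities of those joints along x/y/z give an
18-dimensional feature vector per consecutive frame pair; an optional PCA
step keeps the smallest leading set of components whose cumulative
explained variance reaches 90%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .sequence import SkeletonSequence

__all__ = [
    "SELECTED_JOINTS",
    "FeatureMatrix",
    "PCATransform",
    "select_joints",
    "velocities",
    "fit_pca",
    "apply_pca",
]

#: Canonical joint order for feature columns.
SELECTED_JOINTS: tuple[str, ...] = (
    "SHOULDER_LEFT",
    "ELBOW_LEFT",
    "WRIST_LEFT",
    "HIP_LEFT",
    "KNEE_LEFT",
    "ANKLE_LEFT",
)

_AXES = ("x", "y", "z")


@dataclass
class FeatureMatrix:
    """Per-frame-pair joint velocities (m/s), or their PCA projection.

    ``values`` has one row per consecutive frame pair; columns are labelled
    ``<JOINT>_v<axis>`` in the fixed (shoulder, elbow, wrist, hip, knee,
    ankle) x (x, y, z) order, or ``PC1..PCm`` after projection.
    ``timestamps`` carries the time of the later frame of each pair so rows
    can be aligned with a breath-sampled MET trace.
    """

    values: np.ndarray
    columns: tuple[str, ...]
    timestamps: np.ndarray | None = None
    view: str | None = None
    subject_id: str | None = None
    activity: str | None = None
    speed: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.columns = tuple(self.columns)
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column labels do not match the value matrix width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape[0] != self.values.shape[0]:
                raise ValueError("timestamps length does not match row count")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def replace(self, **changes) -> "FeatureMatrix":
        return replace(self, **changes)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        if self.timestamps is not None:
            df.insert(0, "timestamp_s", self.timestamps)
        return df


def select_joints(
    sequence: SkeletonSequence, joints: tuple[str, ...] = SELECTED_JOINTS
) -> SkeletonSequence:
    """Restrict a sequence to the selected joints, in canonical order.

    Idempotent: re-selecting an already-selected sequence is the identity.
    """
    missing = [j for j in joints if j not in sequence.joint_names]
    if missing:
        raise KeyError(f"sequence lacks required joint(s): {', '.join(missing)}")
    if sequence.joint_names == tuple(joints):
        return sequence
    idx = [sequence.joint_index(j) for j in joints]
    reference = sequence.reference
    return sequence.replace(
        joint_names=tuple(joints),
        positions=sequence.positions[:, idx, :],
        reference=reference,
    )


def velocities(sequence: SkeletonSequence) -> FeatureMatrix:
    """Finite-difference joint velocities between consecutive frames.

    Row k is ``(p_k - p_{k-1}) / (t_k - t_{k-1})`` for every joint and axis;
    N frames give N-1 rows.  Actual timestamps drive the denominator, so
    jittered sampling is handled; duplicate timestamps are rejected.
    """
    if len(sequence) < 2:
        raise ValueError("velocity extraction needs at least 2 frames")
    dt = np.diff(sequence.timestamps)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps: velocity denominator would be zero")
    dp = np.diff(sequence.positions, axis=0)  # (n-1, j, 3)
    vel = dp / dt[:, None, None]
    cols = tuple(f"{j}_v{a}" for j in sequence.joint_names for a in _AXES)
    return FeatureMatrix(
        values=vel.reshape(len(sequence) - 1, -1),
        columns=cols,
        timestamps=sequence.timestamps[1:],
        view=sequence.view,
        subject_id=sequence.subject_id,
        activity=sequence.activity,
        speed=sequence.speed,
    )


@dataclass
class PCATransform:
    """A fitted principal-component projection with the 90% retention rule.

    ``loadings`` is (n_features, retained); columns are orthonormal.
    """

    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    means: np.ndarray
    retained_count: int
    variance_threshold: float
    fitted_on: str = ""
    source_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.explained_variance_ratio = np.asarray(self.explained_variance_ratio, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if not 1 <= self.retained_count <= self.loadings.shape[0]:
            raise ValueError("retained_count out of range")
        if self.loadings.shape[1] != self.retained_count:
            raise ValueError("loadings width must equal retained_count")

    @property
    def n_features(self) -> int:
        return self.loadings.shape[0]

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if values.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} input features, got {values.shape[1]}"
            )
        return (values - self.means) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return scores @ self.loadings.T + self.means

    # -- persistence (small JSON artefact) --------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "means": self.means.tolist(),
            "retained_count": self.retained_count,
            "variance_threshold": self.variance_threshold,
            "fitted_on": self.fitted_on,
            "source_columns": list(self.source_columns),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCATransform":
        payload = json.loads(Path(path).read_text())
        payload["source_columns"] = tuple(payload["source_columns"])
        return cls(**payload)


def fit_pca(
    train: FeatureMatrix | np.ndarray, variance_threshold: float = 0.90
) -> PCATransform:
    """Fit PCA on training rows and keep the smallest leading component set
    whose cumulative explained variance reaches the threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    values = train.values if isinstance(train, FeatureMatrix) else np.atleast_2d(train)
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if np.allclose(values.var(axis=0), 0):
        raise ValueError("zero-variance input: no component explains any variance")
    pca = PCA(n_components=None, svd_solver="full").fit(values)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    retained = int(np.searchsorted(cumulative, variance_threshold - 1e-12) + 1)
    retained = min(retained, pca.components_.shape[0])
    cols = train.columns if isinstance(train, FeatureMatrix) else ()
    fitted_on = (train.view or "") if isinstance(train, FeatureMatrix) else ""
    return PCATransform(
        loadings=pca.components_[:retained].T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        means=pca.mean_,
        retained_count=retained,
        variance_threshold=variance_threshold,
        fitted_on=fitted_on,
        source_columns=tuple(cols),
    )


def apply_pca(transform: PCATransform, features: FeatureMatrix) -> FeatureMatrix:
    """Project a feature matrix onto the retained components."""
    scores = transform.transform(features.values)
    cols = tuple(f"PC{i + 1}" for i in range(transform.retained_count))
    return features.replace(values=scores, columns=cols)
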