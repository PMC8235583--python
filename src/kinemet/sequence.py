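"""Array-backed containers for time-stamped 3-D skeleton recordings.

A :class:`SkeletonSequence` holds one recording bout from one camera view:
an ``(n_frames, n_joints, 3)`` position array in metres plus per-frame
timestamps in seconds.  Coordinates are right-handed with ``y`` vertical and
``z`` the camera depth axis; the origin is the sensor until the sequence is
re-referenced to the body.  The ``stage`` flag records how far through the
preprocessing chain (raw -> recentered -> smoothed -> trimmed) the data are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SkeletonFrame", "SkeletonSequence", "KINECT_V1_JOINTS"]

#: The 20-joint Kinect-v1 skeleton vocabulary.
KINECT_V1_JOINTS: tuple[str, ...] = (
    "HIP_CENTER",
    "SPINE",
    "SHOULDER_CENTER",
    "HEAD",
    "SHOULDER_LEFT",
    "ELBOW_LEFT",
    "WRIST_LEFT",
    "HAND_LEFT",
    "SHOULDER_RIGHT",
    "ELBOW_RIGHT",
    "WRIST_RIGHT",
    "HAND_RIGHT",
    "HIP_LEFT",
    "KNEE_LEFT",
    "ANKLE_LEFT",
    "FOOT_LEFT",
    "HIP_RIGHT",
    "KNEE_RIGHT",
    "ANKLE_RIGHT",
    "FOOT_RIGHT",
)


@dataclass
class SkeletonFrame:
    """A single time-stamped skeleton frame (joint name -> xyz in metres)."""

    timestamp: float
    joints: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not np.isfinite(self.timestamp):
            raise ValueError("frame timestamp must be finite")
        self.joints = {k: np.asarray(v, dtype=float) for k, v in self.joints.items()}
        for name, xyz in self.joints.items():
            if xyz.shape != (3,):
                raise ValueError(f"joint {name!r} must be a 3-vector, got {xyz.shape}")


@dataclass
class SkeletonSequence:
    """An ordered, uniformly-jointed sequence of skeleton frames.

    Parameters
    ----------
    timestamps : (n,) array of seconds, strictly increasing.
    joint_names : names for the second axis of ``positions``.
    positions : (n, n_joints, 3) array of metres.
    frame_rate : nominal sampling rate in Hz (30 for Kinect v1).
    view, subject_id, activity, speed : optional recording metadata.
    stage : preprocessing stage flag.
    """

    timestamps: np.ndarray
    joint_names: tuple[str, ...]
    positions: np.ndarray
    frame_rate: float = 30.0
    view: str | None = None
    subject_id: str | None = None
    activity: str | None = None
    speed: float = 0.0
    stage: str = "raw"
    #: per-frame shoulder-centre reference recorded by :func:`recenter`,
    #: kept so re-applying the operation is a no-op.
    reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.joint_names = tuple(self.joint_names)
        n, j = self.timestamps.shape[0], len(self.joint_names)
        if self.positions.shape != (n, j, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} frames x {j} joints x 3 axes"
            )
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def duration(self) -> float:
        """Recording duration in seconds, counting one full frame period."""
        if len(self) == 0:
            return 0.0
        span = float(self.timestamps[-1] - self.timestamps[0])
        return span + 1.0 / self.frame_rate

    def joint_index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"joint {name!r} not present in sequence") from None

    def joint(self, name: str) -> np.ndarray:
        """The (n, 3) trajectory of one named joint."""
        return self.positions[:, self.joint_index(name), :]

    def frame(self, k: int) -> SkeletonFrame:
        return SkeletonFrame(
            timestamp=float(self.timestamps[k]),
            joints={name: self.positions[k, i].copy() for i, name in enumerate(self.joint_names)},
        )

    def replace(self, **changes) -> "SkeletonSequence":
        return replace(self, **changes)

    @classmethod
    def from_frames(
        cls,
        frames: list[SkeletonFrame],
        *,
        frame_rate: float = 30.0,
        **metadata,
    ) -> "SkeletonSequence":
        """Build a sequence from :class:`SkeletonFrame` objects (shared joint set)."""
        if not frames:
            raise ValueError("cannot build a sequence from zero frames")
        names = tuple(frames[0].joints)
        ts, pos = [], []
        for f in frames:
            if tuple(f.joints) != names:
                raise ValueError("all frames must share one joint set, in order")
            ts.append(f.timestamp)
            pos.append([f.joints[n] for n in names])
        return cls(
            timestamps=np.asarray(ts, dtype=float),
            joint_names=names,
            positions=np.asarray(pos, dtype=float),
            frame_rate=frame_rate,
            **metadata,
        )
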