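"""Skeleton preprocessing: body-centred re-referencing, moving-average
denoising, and steady-state trimming.

The default chain is ``recenter -> smooth -> trim_steady_state``:

1. every joint is translated so the shoulder-centre joint of the same frame
   sits at the origin, removing whole-body treadmill drift;
2. each coordinate is replaced by the centred 5-point moving average over
   frames k-2..k+2, attenuating skeletal-tracking jitter (variance of
   i.i.d. noise drops by a factor of 5);
3. the non-steady-state head of the bout (default: first 3 minutes) is
   discarded and a fixed steady-state window (default: next 2 minutes) kept.
"""

from __future__ import annotations

import numpy as np

from .sequence import SkeletonFrame, SkeletonSequence

__all__ = [
    "SHOULDER_CENTER",
    "recenter",
    "recenter_frame",
    "smooth",
    "trim_steady_state",
    "preprocess",
]

SHOULDER_CENTER = "SHOULDER_CENTER"
_SMOOTH_HALF_WIDTH = 2  # frames either side of k in the moving average


def recenter_frame(frame: SkeletonFrame, reference_joint: str = SHOULDER_CENTER) -> SkeletonFrame:
    """Translate one frame so the reference joint sits at the origin."""
    if reference_joint not in frame.joints:
        raise KeyError(
            f"frame at t={frame.timestamp:.3f}s lacks the {reference_joint} joint "
            "needed for re-referencing"
        )
    ref = frame.joints[reference_joint].copy()
    return SkeletonFrame(
        timestamp=frame.timestamp,
        joints={name: xyz - ref for name, xyz in frame.joints.items()},
    )


def recenter(sequence: SkeletonSequence, reference_joint: str = SHOULDER_CENTER) -> SkeletonSequence:
    """Re-reference every frame to its own shoulder-centre position.

    Each joint i becomes (xi - xr, yi - yr, zi - zr) where (xr, yr, zr) is
    the reference joint of the same frame; the reference joint maps exactly
    to the origin.  The per-frame reference trajectory is recorded on the
    output so applying the operation again is a no-op.
    """
    if sequence.reference is not None:
        return sequence  # already body-centred
    try:
        ref = sequence.joint(reference_joint)
    except KeyError:
        raise KeyError(
            f"sequence lacks the {reference_joint} joint needed for re-referencing"
        ) from None
    positions = sequence.positions - ref[:, None, :]
    return sequence.replace(positions=positions, reference=ref.copy(), stage="recentered")


def smooth(sequence: SkeletonSequence) -> SkeletonSequence:
    """Centred 5-point moving average of every coordinate.

    Interior frame k is replaced by the mean of frames k-2..k+2 per joint
    per axis.  The first and last two frames have no full window and are
    dropped (no padding is invented); interior timestamps are unchanged.
    """
    n = len(sequence)
    h = _SMOOTH_HALF_WIDTH
    width = 2 * h + 1
    if n < width:
        raise ValueError(f"smoothing needs at least {width} frames, got {n}")
    kernel = np.full(width, 1.0 / width)
    flat = sequence.positions.reshape(n, -1)
    out = np.empty((n - 2 * h, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.convolve(flat[:, c], kernel, mode="valid")
    positions = out.reshape(n - 2 * h, len(sequence.joint_names), 3)
    reference = None if sequence.reference is None else sequence.reference[h:-h]
    return sequence.replace(
        timestamps=sequence.timestamps[h:-h],
        positions=positions,
        reference=reference,
        stage="smoothed",
    )


def trim_steady_state(
    sequence: SkeletonSequence, discard_min: float = 3.0, keep_min: float = 2.0
) -> SkeletonSequence:
    """Keep only the steady-state window of a bout.

    Frames whose time since the first frame lies in
    ``[discard_min, discard_min + keep_min)`` minutes are retained — at
    30 Hz the default 3-discard/2-keep split of a 5-minute bout keeps
    exactly 3600 frames.  Sequences whose duration does not cover the full
    window are rejected.
    """
    if discard_min < 0 or keep_min <= 0:
        raise ValueError("discard_min must be >= 0 and keep_min > 0")
    needed = (discard_min + keep_min) * 60.0
    if sequence.duration + 1e-9 < needed:
        raise ValueError(
            f"sequence covers {sequence.duration:.1f}s but trimming needs "
            f"{needed:.1f}s ({discard_min} min discard + {keep_min} min keep)"
        )
    rel = sequence.timestamps - sequence.timestamps[0]
    mask = (rel >= discard_min * 60.0) & (rel < needed)
    reference = None if sequence.reference is None else sequence.reference[mask]
    return sequence.replace(
        timestamps=sequence.timestamps[mask],
        positions=sequence.positions[mask],
        reference=reference,
        stage="trimmed",
    )


def preprocess(
    sequence: SkeletonSequence, discard_min: float = 3.0, keep_min: float = 2.0
) -> SkeletonSequence:
    """The default chain: recenter, smooth, trim to the steady state."""
    return trim_steady_state(smooth(recenter(sequence)), discard_min, keep_min)
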