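"""Synthetic skeletal-motion and metabolic data generator.

Emulates a treadmill protocol recorded by depth cameras: a cohort of
subjects each performs standing, walking (4.8/5.6/6.4 km/h) and running
(8.0/8.3 km/h) bouts while three cameras (side, rear-side, rear; tripod
0.9 m high, ~2 m standoff) record a 20-joint skeleton at 30 Hz, and a
breath-by-breath calorimeter records energy expenditure in MET units
(1 MET = 1 kcal per kg body mass per hour).

The kinematic model is deliberately stylised, not a biomechanical gait
simulation: standing is a static pose plus slow postural sway; walking and
running superpose sinusoidal limb oscillations at a speed-dependent cadence
(contralateral limbs counter-phased, arms counter-phased to the same-side
leg, a 2:1-frequency whole-body vertical bounce) on the static pose, plus a
slow fore-aft body drift mimicking imperfect treadmill station-keeping.
Skeletal tracking noise is additive isotropic Gaussian per joint per frame.

Ground-truth MET traces follow standard walking/running metabolic
equations -- MET = (c.v + 3.5)/3.5 with v in m/min and c = 0.1 (walk) or
0.2 (run) -- plus a per-subject additive offset and breath-level noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .sequence import KINECT_V1_JOINTS, SkeletonSequence

__all__ = [
    "SubjectProfile",
    "ActivityBout",
    "CameraView",
    "MotionParams",
    "METParams",
    "METTrace",
    "CohortParams",
    "Protocol",
    "CANONICAL_VIEWS",
    "TREADMILL_BOUTS",
    "sample_cohort",
    "met_ground_truth",
    "generate_bout",
    "generate_sequence",
    "project_to_view",
    "simulate_protocol",
    "SimulatedRecording",
]

STANDING, WALKING, RUNNING = "standing", "walking", "running"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics of one simulated participant."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years
    weight: float  # kg
    body_fat: float  # percent

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if not 0.0 <= self.body_fat <= 100.0:
            raise ValueError("body_fat must lie in [0, 100] percent")


@dataclass(frozen=True)
class ActivityBout:
    """One protocol entry: an activity at a treadmill speed for a duration."""

    activity: str  # standing | walking | running
    speed: float  # km/h (0 for standing)
    duration: float = 5.0  # minutes
    rest_after: float = 0.0  # minutes

    def __post_init__(self) -> None:
        if self.activity not in (STANDING, WALKING, RUNNING):
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.activity == STANDING and self.speed != 0:
            raise ValueError("standing bouts must have speed 0")
        if self.activity != STANDING and self.speed == 0:
            raise ValueError(f"{self.activity} bouts need a positive speed")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def intensity(self) -> str:
        return {STANDING: "light", WALKING: "moderate", RUNNING: "vigorous"}[self.activity]


@dataclass(frozen=True)
class CameraView:
    """A depth-camera placement: yaw about the vertical axis relative to the
    subject's facing direction (0 deg = directly behind), tripod height and
    horizontal standoff in metres."""

    name: str
    yaw: float  # degrees
    height: float = 0.9  # m
    standoff: float = 2.0  # m

    def __post_init__(self) -> None:
        if self.height <= 0 or self.standoff <= 0:
            raise ValueError("camera height and standoff must be positive")


#: Canonical three-camera arrangement: rear camera looks along the walking
#: direction (yaw 0), the side camera is perpendicular to it.
CANONICAL_VIEWS: tuple[CameraView, ...] = (
    CameraView("side", yaw=90.0),
    CameraView("rear_side", yaw=45.0),
    CameraView("rear", yaw=0.0),
)

#: Default treadmill protocol: 5-min bouts from light to vigorous.
TREADMILL_BOUTS: tuple[ActivityBout, ...] = (
    ActivityBout(STANDING, 0.0, 5.0, rest_after=0.0),
    ActivityBout(WALKING, 4.8, 5.0, rest_after=5.0),
    ActivityBout(WALKING, 5.6, 5.0, rest_after=5.0),
    ActivityBout(WALKING, 6.4, 5.0, rest_after=5.0),
    ActivityBout(RUNNING, 8.0, 5.0, rest_after=10.0),
    ActivityBout(RUNNING, 8.3, 5.0, rest_after=10.0),
)


def _default_amplitudes() -> dict[str, float]:
    # Fore-aft oscillation amplitude (m) at the 5 km/h reference speed; the
    # effective amplitude scales linearly with treadmill speed.
    return {
        "ANKLE": 0.30,
        "FOOT": 0.32,
        "KNEE": 0.18,
        "HIP": 0.03,
        "WRIST": 0.16,
        "HAND": 0.18,
        "ELBOW": 0.10,
        "SHOULDER": 0.03,
    }


@dataclass
class MotionParams:
    """Tunable parameters of the kinematic model.

    ``cadence_base + cadence_speed_gain * speed`` gives the stride (per-leg)
    frequency in Hz; at the protocol speeds this spans ~0.9 Hz (slow walk)
    to ~1.4 Hz (run), in the range treadmill gait studies report.
    """

    cadence_base: float = 0.25  # Hz
    cadence_speed_gain: float = 0.14  # Hz per (km/h)
    limb_amplitudes: dict[str, float] = field(default_factory=_default_amplitudes)
    amplitude_ref_speed: float = 5.0  # km/h at which limb_amplitudes apply
    lift_fraction: float = 0.2  # vertical lift amplitude as fraction of swing
    bounce_amplitude: float = 0.025  # m, whole-body vertical bounce at 2x cadence
    sway_sd: float = 0.02  # m, standing postural sway amplitude
    sway_freq: float = 0.25  # Hz
    drift_amplitude: float = 0.05  # m, fore-aft station-keeping drift
    drift_freq: float = 0.08  # Hz
    sensor_noise_sd: float = 0.005  # m, skeletal tracking jitter per axis
    frame_rate: float = 30.0  # Hz

    def __post_init__(self) -> None:
        for name in ("bounce_amplitude", "sway_sd", "drift_amplitude", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(a < 0 for a in self.limb_amplitudes.values()):
            raise ValueError("limb amplitudes must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def cadence(self, speed: float) -> float:
        """Stride frequency (Hz) at a treadmill speed in km/h."""
        return self.cadence_base + self.cadence_speed_gain * speed


@dataclass
class METParams:
    """Parameters of the ground-truth MET model.

    Walking/running METs follow the standard metabolic equations
    ``VO2 = c * v + 3.5`` (mL O2 / kg / min, v in m/min, c = 0.1 walking /
    0.2 running) divided by the 3.5 mL/kg/min resting rate; quiet standing
    is a fixed 1.3 MET.  A per-subject Gaussian offset (SD
    ``subject_effect_sd``) shifts every activity of that subject; breath
    samples add Gaussian noise with SD ``breath_noise_sd`` at one sample per
    ``breath_interval`` seconds.
    """

    standing_met: float = 1.3
    rest_vo2: float = 3.5  # mL O2 / kg / min per MET
    walk_coeff: float = 0.1  # mL O2 / kg / m
    run_coeff: float = 0.2
    subject_effect_sd: float = 0.2  # MET
    breath_noise_sd: float = 0.1  # MET
    breath_interval: float = 3.0  # s
    effect_seed: int = 0  # salt for the per-subject offset stream


@dataclass
class METTrace:
    """A breath-sampled energy-expenditure trace in MET units."""

    timestamps: np.ndarray  # s
    met_values: np.ndarray  # MET

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.met_values = np.asarray(self.met_values, dtype=float)
        if self.timestamps.shape != self.met_values.shape:
            raise ValueError("timestamps and met_values must have equal length")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("trace timestamps must be strictly increasing")
        if np.any(self.met_values <= 0):
            raise ValueError("MET values must be positive")

    def at_times(self, times: np.ndarray) -> np.ndarray:
        """Previous-value (step) interpolation of the trace at given times."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.timestamps, times, side="right") - 1
        return self.met_values[np.clip(idx, 0, len(self.met_values) - 1)]


@dataclass
class CohortParams:
    """Means/SDs of the cohort anthropometrics and the male fraction."""

    age_mean: float = 21.90
    age_sd: float = 1.55
    weight_mean: float = 60.20
    weight_sd: float = 7.60
    body_fat_mean: float = 20.69
    body_fat_sd: float = 7.37
    male_fraction: float = 10.0 / 21.0

    # physiological truncation bounds for the sampling distributions
    age_bounds: tuple[float, float] = (16.0, 80.0)
    weight_bounds: tuple[float, float] = (35.0, 150.0)
    body_fat_bounds: tuple[float, float] = (3.0, 60.0)

    def __post_init__(self) -> None:
        for name in ("age_sd", "weight_sd", "body_fat_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _truncnorm_sample(rng, mean, sd, bounds, size):
    if sd == 0:
        return np.full(size, float(mean))
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(
    n: int,
    cohort_params: CohortParams | None = None,
    seed: int = 0,
    n_male: int | None = None,
) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles from truncated-normal anthropometric
    distributions; deterministic for a fixed seed.

    ``n_male`` fixes the sex split exactly (e.g. 10 of 21); by default it is
    rounded from ``cohort_params.male_fraction``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    p = cohort_params or CohortParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ages = _truncnorm_sample(rng, p.age_mean, p.age_sd, p.age_bounds, n)
    weights = _truncnorm_sample(rng, p.weight_mean, p.weight_sd, p.weight_bounds, n)
    fats = _truncnorm_sample(rng, p.body_fat_mean, p.body_fat_sd, p.body_fat_bounds, n)
    if n_male is None:
        n_male = int(round(p.male_fraction * n))
    if not 0 <= n_male <= n:
        raise ValueError("n_male must lie in [0, n]")
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    return [
        SubjectProfile(
            subject_id=f"S{i:03d}",
            sex=str(sexes[i]),
            age=float(ages[i]),
            weight=float(weights[i]),
            body_fat=float(fats[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# MET ground truth
# ---------------------------------------------------------------------------


def _subject_offset(subject: SubjectProfile, params: METParams) -> float:
    """Per-subject MET offset, stable across bouts and views.

    Keyed by a CRC of the subject id plus a configurable salt so that the
    same subject gets the same offset in every bout without the profile
    having to carry extra state.
    """
    key = zlib.crc32(subject.subject_id.encode("utf-8"))
    rng = np.random.default_rng(np.random.SeedSequence(params.effect_seed, spawn_key=(key,)))
    return float(params.subject_effect_sd * rng.standard_normal())


def met_ground_truth(
    activity: str,
    speed: float,
    subject: SubjectProfile | None = None,
    params: METParams | None = None,
) -> float:
    """Ground-truth MET for an activity at a treadmill speed.

    Returns the metabolic-equation base value plus the subject's offset
    (zero when no subject is given).  Monotone increasing in speed within
    each gait, and standing < walking < running at the default protocol
    speeds for every subject.
    """
    params = params or METParams()
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if activity == STANDING:
        base = params.standing_met
    elif activity in (WALKING, RUNNING):
        v = speed * 1000.0 / 60.0  # km/h -> m/min
        coeff = params.walk_coeff if activity == WALKING else params.run_coeff
        base = (coeff * v + params.rest_vo2) / params.rest_vo2
    else:
        raise ValueError(f"unknown activity {activity!r}")
    if subject is not None:
        base += _subject_offset(subject, params)
    return base


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

# Static reference pose, world frame: x lateral (subject's left positive),
# y vertical from the floor, z the facing/walking direction.  Metres, for a
# roughly 1.7 m adult.
_BASE_POSE: dict[str, tuple[float, float, float]] = {
    "HIP_CENTER": (0.00, 0.95, 0.00),
    "SPINE": (0.00, 1.15, 0.00),
    "SHOULDER_CENTER": (0.00, 1.40, 0.00),
    "HEAD": (0.00, 1.65, 0.00),
    "SHOULDER_LEFT": (0.20, 1.40, 0.00),
    "ELBOW_LEFT": (0.25, 1.10, 0.00),
    "WRIST_LEFT": (0.25, 0.85, 0.02),
    "HAND_LEFT": (0.25, 0.78, 0.05),
    "SHOULDER_RIGHT": (-0.20, 1.40, 0.00),
    "ELBOW_RIGHT": (-0.25, 1.10, 0.00),
    "WRIST_RIGHT": (-0.25, 0.85, 0.02),
    "HAND_RIGHT": (-0.25, 0.78, 0.05),
    "HIP_LEFT": (0.10, 0.95, 0.00),
    "KNEE_LEFT": (0.12, 0.50, 0.00),
    "ANKLE_LEFT": (0.12, 0.10, 0.00),
    "FOOT_LEFT": (0.12, 0.05, 0.12),
    "HIP_RIGHT": (-0.10, 0.95, 0.00),
    "KNEE_RIGHT": (-0.12, 0.50, 0.00),
    "ANKLE_RIGHT": (-0.12, 0.10, 0.00),
    "FOOT_RIGHT": (-0.12, 0.05, 0.12),
}

_LEG_JOINTS = {"HIP", "KNEE", "ANKLE", "FOOT"}
_ARM_JOINTS = {"SHOULDER", "ELBOW", "WRIST", "HAND"}

#: Within-limb phase offsets (radians) of the fore-aft oscillation.  Real
#: gait is not a single in-phase oscillator: knee flexion leads the ankle
#: swing and distal arm segments lag the shoulder, which is what gives the
#: instantaneous 18-d velocity vector its elliptical (rather than
#: degenerate, line-collapsed) trajectory over a stride.
_PART_PHASE: dict[str, float] = {
    "ANKLE": 0.0,
    "FOOT": -0.35,
    "KNEE": 1.2,
    "HIP": 0.4,
    "SHOULDER": 0.2,
    "ELBOW": 0.55,
    "WRIST": 0.9,
    "HAND": 1.1,
}


def _joint_part_side(name: str) -> tuple[str, str | None]:
    if name.endswith("_LEFT"):
        return name[:-5], "left"
    if name.endswith("_RIGHT"):
        return name[:-6], "right"
    return name, None


def _world_trajectories(
    bout: ActivityBout, params: MotionParams, n: int, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """World-frame positions (n, 20, 3) before view projection and noise."""
    pos = np.empty((n, len(KINECT_V1_JOINTS), 3))
    base = np.array([_BASE_POSE[j] for j in KINECT_V1_JOINTS])
    pos[:] = base[None, :, :]

    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    sway_phases = rng.uniform(0.0, 2.0 * np.pi, size=2)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)

    # whole-body postural sway (x and z) and fore-aft drift
    sway_x = params.sway_sd * np.sin(2 * np.pi * params.sway_freq * t + sway_phases[0])
    sway_z = params.sway_sd * np.sin(2 * np.pi * params.sway_freq * t + sway_phases[1])
    pos[:, :, 0] += sway_x[:, None]
    pos[:, :, 2] += sway_z[:, None]

    if bout.activity != STANDING:
        f = params.cadence(bout.speed)
        scale = bout.speed / params.amplitude_ref_speed
        drift = params.drift_amplitude * np.sin(2 * np.pi * params.drift_freq * t + drift_phase)
        pos[:, :, 2] += drift[:, None]
        # whole-body vertical bounce at twice the stride frequency
        bounce = params.bounce_amplitude * scale * np.sin(2 * np.pi * 2 * f * t + 2 * phase0)
        pos[:, :, 1] += bounce[:, None]
        for i, name in enumerate(KINECT_V1_JOINTS):
            part, side = _joint_part_side(name)
            if side is None or part not in params.limb_amplitudes:
                continue
            amp = params.limb_amplitudes[part] * scale
            # left leg at phase0; right leg counter-phased; arms swing
            # counter-phase to the same-side leg; within a limb, segments
            # carry their biomechanical phase offsets.
            phase = phase0 + _PART_PHASE[part] + (0.0 if side == "left" else np.pi)
            if part in _ARM_JOINTS:
                phase += np.pi
            pos[:, i, 2] += amp * np.sin(2 * np.pi * f * t + phase)
            if part in _LEG_JOINTS and part != "HIP":
                # the foot is highest mid-swing: vertical lift lags the
                # fore-aft swing by a quarter cycle
                lift = params.lift_fraction * amp
                pos[:, i, 1] += lift * np.sin(2 * np.pi * f * t + phase - np.pi / 2)
    return pos


def _yaw_matrix(yaw_deg: float) -> np.ndarray:
    th = np.deg2rad(yaw_deg)
    c, s = np.cos(th), np.sin(th)
    # rotation about the vertical (y) axis
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def project_to_view(world_sequence: SkeletonSequence, view: CameraView) -> SkeletonSequence:
    """Express a world-frame sequence in a camera's coordinate frame.

    Rigid motion: rotation about the vertical axis by the view yaw followed
    by translation so the origin sits at the sensor (camera height above the
    floor, standoff in front of the subject).  Inter-joint distances are
    preserved exactly.
    """
    rot = _yaw_matrix(view.yaw)
    shifted = world_sequence.positions @ rot.T
    shifted = shifted + np.array([0.0, -view.height, view.standoff])
    return world_sequence.replace(positions=shifted, view=view.name)


def generate_bout(
    subject: SubjectProfile,
    bout: ActivityBout,
    params: MotionParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    met_params: METParams | None = None,
) -> tuple[SkeletonSequence, METTrace]:
    """Simulate the world-frame motion and the calorimeter trace of one bout.

    The returned sequence is noise-free and in the world frame; cameras
    observe it through :func:`project_to_view` (or :func:`generate_sequence`,
    which also adds per-view sensor noise).  The MET trace belongs to the
    subject, not a camera, so it is shared by every view of the bout.
    """
    params = params or MotionParams()
    met_params = met_params or METParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    motion_rng, breath_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    n = int(round(bout.duration * 60.0 * params.frame_rate))
    if n < 1:
        raise ValueError("bout too short for a single frame")
    t = np.arange(n) / params.frame_rate

    world = _world_trajectories(bout, params, n, t, motion_rng)
    seq = SkeletonSequence(
        timestamps=t,
        joint_names=KINECT_V1_JOINTS,
        positions=world,
        frame_rate=params.frame_rate,
        view="world",
        subject_id=subject.subject_id,
        activity=bout.activity,
        speed=bout.speed,
    )

    true_met = met_ground_truth(bout.activity, bout.speed, subject, met_params)
    breath_t = np.arange(0.0, bout.duration * 60.0, met_params.breath_interval)
    met = true_met + met_params.breath_noise_sd * breath_rng.standard_normal(breath_t.shape)
    met = np.maximum(met, 0.1)  # calorimetry never reports non-positive MET
    return seq, METTrace(timestamps=breath_t, met_values=met)


def _add_sensor_noise(
    seq: SkeletonSequence, view: CameraView, params: MotionParams, ss: np.random.SeedSequence
) -> SkeletonSequence:
    if params.sensor_noise_sd == 0:
        return seq
    # each camera has its own tracking-noise stream, keyed by the view name
    key = zlib.crc32(view.name.encode("utf-8"))
    child = np.random.SeedSequence(ss.entropy, spawn_key=tuple(ss.spawn_key) + (2, key))
    rng = np.random.default_rng(child)
    return seq.replace(
        positions=seq.positions + rng.normal(0.0, params.sensor_noise_sd, size=seq.positions.shape)
    )


def generate_sequence(
    subject: SubjectProfile,
    bout: ActivityBout,
    view: CameraView,
    params: MotionParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    met_params: METParams | None = None,
) -> tuple[SkeletonSequence, METTrace]:
    """Simulate one recording bout as seen from one camera view.

    Returns the camera-frame skeleton sequence (with additive per-view
    sensor noise) and the aligned breath-sampled MET ground-truth trace.
    Calling this with the same seed but different views reuses the same
    underlying motion and trace — three cameras film one performance.
    Bit-identical output for a fixed seed and parameter set.
    """
    params = params or MotionParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    world, trace = generate_bout(subject, bout, params, seed=ss, met_params=met_params)
    seq = project_to_view(world, view)
    seq = _add_sensor_noise(seq, view, params, ss)
    return seq, trace


# ---------------------------------------------------------------------------
# protocol-level simulation
# ---------------------------------------------------------------------------


@dataclass
class Protocol:
    """A full study description: cohort, bouts, camera views, parameters."""

    n_subjects: int = 21
    cohort: CohortParams = field(default_factory=CohortParams)
    bouts: tuple[ActivityBout, ...] = TREADMILL_BOUTS
    views: tuple[CameraView, ...] = CANONICAL_VIEWS
    motion: MotionParams = field(default_factory=MotionParams)
    met: METParams = field(default_factory=METParams)

    def scaled(self, n_subjects: int, duration: float) -> "Protocol":
        """A smaller copy: fewer subjects and shorter bouts, same structure."""
        bouts = tuple(replace(b, duration=duration) for b in self.bouts)
        return replace(self, n_subjects=n_subjects, bouts=bouts)


@dataclass
class SimulatedRecording:
    subject: SubjectProfile
    bout: ActivityBout
    view: CameraView
    sequence: SkeletonSequence
    met_trace: METTrace


def simulate_protocol(protocol: Protocol, seed: int = 0) -> list[SimulatedRecording]:
    """Simulate every subject x bout x view cell of a protocol.

    The root seed is split hierarchically per (subject, bout, view) so the
    stream feeding one recording does not depend on how many other bouts or
    views are configured.
    """
    cohort = sample_cohort(protocol.n_subjects, protocol.cohort, seed=seed)
    out: list[SimulatedRecording] = []
    for si, subject in enumerate(cohort):
        for bi, bout in enumerate(protocol.bouts):
            ss = np.random.SeedSequence(seed, spawn_key=(1, si, bi))
            world, trace = generate_bout(
                subject, bout, protocol.motion, seed=ss, met_params=protocol.met
            )
            for view in protocol.views:
                seq = project_to_view(world, view)
                seq = _add_sensor_noise(seq, view, protocol.motion, ss)
                out.append(SimulatedRecording(subject, bout, view, seq, trace))
    return out
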