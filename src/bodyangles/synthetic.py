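"""Seeded parametric generator of labeled skeleton sequences.

Emulates Kinect-v1-style recordings of the eight evaluated activities:
Stand, Stay Seated, Walk [D], Walk Backwards [D] (the sink activities) and
Drink [D], Grab Object [D], Leg Flexion [I], Leg Circular Swing [I] (the
bounded activities). Each activity is a deterministic kinematic script — a
function of body proportions and a phase in [0, 1] — on top of which the
noise model adds per-joint Gaussian jitter and occasional large "inference"
spikes, the two characteristic Kinect error modes (positioning imprecision
while still, and invented positions for occluded joints).

Scripts are defined in joint-angle space, so bone directions (the features
the recognizer uses) are independent of body size. Leg activities include a
compensatory forward trunk lean, and the optional balance-sway transform
superimposes an unconscious forward reach of the right arm shaped like the
Grab Object arc — the mechanism hypothesized to confuse leg activities with
Grab Object on a device that only sees joint angles.

The sensor model is joint-dependent: trunk joints are tracked most stably,
while distal extremity joints suffer the most positioning jitter and are the
most likely to be "inferred" (spiked) when occluded. A per-repetition
execution-scale factor models the fact that a person never reproduces the
key sample's amplitudes exactly.

Movement scripts deliberately end at an activity-characteristic pose rather
than returning to rest: decisions are taken while the motion is in progress,
and a window ending in the neutral stance would trivially resemble Stand.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .errors import ConfigurationError, ValidationError
from .recognizer import (
    ActivitySpec,
    ActivityTemplate,
    Extremity,
    JointSetVariant,
    Laterality,
    variant_joints,
)
from .skeleton import (
    MIRROR_JOINT,
    Bone,
    Joint,
    SkeletonFrame,
    SkeletonSequence,
)

__all__ = [
    "BodyModel",
    "NoiseParams",
    "ActivityScript",
    "ACTIVITIES",
    "ACTIVITY_ORDER",
    "SINK_ACTIVITIES",
    "LEG_ACTIVITIES",
    "DEFAULT_BODY_RANGES",
    "DEFAULT_FPS",
    "generate_participant",
    "generate_sequence",
    "with_balance_sway",
    "make_template",
    "sequence_seed",
]

DEFAULT_FPS = 30.0

#: Segment-length sampling ranges in meters (left/right symmetric).
DEFAULT_BODY_RANGES: dict[str, tuple[float, float]] = {
    "forearm": (0.22, 0.28),
    "foot": (0.12, 0.18),
    "hand": (0.07, 0.09),
    "hip_half": (0.09, 0.12),
    "neck": (0.20, 0.25),
    "shank": (0.36, 0.44),
    "shoulder_half": (0.17, 0.21),
    "thigh": (0.38, 0.46),
    "trunk_lower": (0.22, 0.28),
    "trunk_upper": (0.22, 0.28),
    "upper_arm": (0.25, 0.32),
}

_ANKLE_HEIGHT = 0.08  # ankle joint height above the floor, meters
_SENSOR_DISTANCE = 2.5  # initial pelvis distance from the sensor, meters
_SPIKE_SPEED_SCALE = 0.25  # m/s of pelvis-relative motion giving the base spike rate

#: Relative tracking unreliability per joint. The trunk moves little and is
#: never occluded, so it is the most stable; distal joints are the least.
#: Scales both the jitter standard deviation and the spike probability.
JOINT_RELIABILITY: dict[Joint, float] = {
    j: w
    for names, w in (
        (("HIP_CENTER", "SPINE", "SHOULDER_CENTER", "HEAD"), 0.4),
        (("SHOULDER_L", "SHOULDER_R", "HIP_L", "HIP_R"), 0.7),
        (("ELBOW_L", "ELBOW_R", "KNEE_L", "KNEE_R"), 1.0),
        (("WRIST_L", "WRIST_R", "ANKLE_L", "ANKLE_R"), 1.3),
        (("HAND_L", "HAND_R", "FOOT_L", "FOOT_R"), 1.6),
    )
    for j in (Joint[n] for n in names)
}


@dataclass(frozen=True)
class BodyModel:
    """Per-participant body proportions (meters), left/right symmetric."""

    participant_id: str
    upper_arm: float
    forearm: float
    hand: float
    thigh: float
    shank: float
    foot: float
    trunk_lower: float
    trunk_upper: float
    neck: float
    shoulder_half: float
    hip_half: float

    def __post_init__(self) -> None:
        for name in DEFAULT_BODY_RANGES:
            if getattr(self, name) <= 0:
                raise ValidationError(f"segment {name} must be positive")

    @property
    def stance_height(self) -> float:
        """Standing pelvis height above the floor."""
        return self.thigh + self.shank + _ANKLE_HEIGHT

    @property
    def segment_lengths(self) -> dict[Bone, float]:
        """Length of every topology bone implied by the proportions."""
        J = Joint
        out = {
            Bone(J.HIP_CENTER, J.SPINE): self.trunk_lower,
            Bone(J.SPINE, J.SHOULDER_CENTER): self.trunk_upper,
            Bone(J.SHOULDER_CENTER, J.HEAD): self.neck,
            Bone(J.SHOULDER_L, J.SHOULDER_R): 2 * self.shoulder_half,
            Bone(J.HIP_L, J.HIP_R): 2 * self.hip_half,
        }
        for side in ("L", "R"):
            out[Bone(J.SHOULDER_CENTER, J[f"SHOULDER_{side}"])] = self.shoulder_half
            out[Bone(J[f"SHOULDER_{side}"], J[f"ELBOW_{side}"])] = self.upper_arm
            out[Bone(J[f"ELBOW_{side}"], J[f"WRIST_{side}"])] = self.forearm
            out[Bone(J[f"WRIST_{side}"], J[f"HAND_{side}"])] = self.hand
            out[Bone(J.HIP_CENTER, J[f"HIP_{side}"])] = self.hip_half
            out[Bone(J[f"HIP_{side}"], J[f"KNEE_{side}"])] = self.thigh
            out[Bone(J[f"KNEE_{side}"], J[f"ANKLE_{side}"])] = self.shank
            out[Bone(J[f"ANKLE_{side}"], J[f"FOOT_{side}"])] = self.foot
        return out


def generate_participant(
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str | None = None,
) -> BodyModel:
    """Sample a body uniformly within ``ranges``; reproducible per seed."""
    ranges = dict(DEFAULT_BODY_RANGES if ranges is None else ranges)
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValidationError(f"inverted range for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    draws = {
        name: float(rng.uniform(lo, hi))
        for name, (lo, hi) in sorted(ranges.items())
    }
    if participant_id is None:
        participant_id = f"P{seed}" if isinstance(seed, int) else "P?"
    return BodyModel(participant_id=participant_id, **draws)


@dataclass(frozen=True)
class NoiseParams:
    """Sensor-error model: Gaussian jitter plus rare inference spikes.

    ``jitter_sd`` and ``spike_prob`` are base values, scaled per joint by
    :data:`JOINT_RELIABILITY` (trunk stablest, distal joints worst). Jitter
    is always present ("positioning imprecision even when the user is
    still"); spikes model occlusion/inference failures, which occur on
    joints in motion — a joint's spike probability is additionally scaled by
    its speed relative to the pelvis (zero for a static joint, saturating at
    twice the base rate for fast motion).

    ``sway_amplitude`` is the peak forward displacement (meters) of the
    unconscious balance reach superimposed on leg activities; it models the
    compensatory arm motion of a person balancing on one leg, not a sensor
    error, and is applied via :func:`with_balance_sway`. The default is a
    pronounced reach comparable to the deliberate Grab Object one.

    ``exec_sd`` is the fractional standard deviation of the per-repetition
    execution scale: each repetition multiplies every script joint angle by
    one draw from N(1, exec_sd), because a person never reproduces the key
    sample's amplitudes exactly (only the speed is kept).
    """

    jitter_sd: float = 0.01  # m per axis per joint, Kinect-v1 order of magnitude
    spike_prob: float = 0.02  # per joint per frame
    spike_sd: float = 0.10  # m
    sway_amplitude: float = 0.55  # m; peak reach of the balancing arm
    exec_sd: float = 0.10  # fractional amplitude variability per repetition
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self) -> None:
        if min(self.jitter_sd, self.spike_sd, self.sway_amplitude, self.exec_sd) < 0:
            raise ValidationError("noise magnitudes must be non-negative")
        if not (0.0 <= self.spike_prob <= 1.0):
            raise ValidationError("spike_prob must be a probability")

    @classmethod
    def zero(cls, seed: int | np.random.SeedSequence = 0) -> "NoiseParams":
        return cls(jitter_sd=0.0, spike_prob=0.0, spike_sd=0.0, sway_amplitude=0.0,
                   exec_sd=0.0, seed=seed)


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def _dir(sag: float, lat: float, x_sign: float) -> np.ndarray:
    """Unit direction of a hanging segment.

    ``sag`` is the forward (sagittal) angle from straight down, ``lat`` the
    outward (abduction) angle; ``x_sign`` +1 for the right side, -1 for the
    left. Forward is -z (toward the sensor), up is +y.
    """
    cl = math.cos(lat)
    return np.array(
        [x_sign * math.sin(lat), -math.cos(sag) * cl, -math.sin(sag) * cl]
    )


_FOOT_SAG = math.radians(78.0)  # foot points forward, slightly downhill


@dataclass
class Pose:
    """Joint-angle parameters of one frame; all angles in radians."""

    trunk_pitch: float = 0.0
    sh_sag: tuple[float, float] = (0.0, 0.0)  # (left, right) shoulder flexion
    sh_lat: tuple[float, float] = (0.0, 0.0)
    elb: tuple[float, float] = (0.0, 0.0)
    hip_sag: tuple[float, float] = (0.0, 0.0)
    hip_lat: tuple[float, float] = (0.0, 0.0)
    knee: tuple[float, float] = (0.0, 0.0)
    pelvis_height: float | None = None  # default: standing
    pelvis_dz: float = 0.0  # translation toward (-) / away from (+) the sensor


def build_frame(body: BodyModel, pose: Pose, timestamp: float = 0.0) -> SkeletonFrame:
    """Forward kinematics: joint-angle pose -> 20 joint positions."""
    h = body.stance_height if pose.pelvis_height is None else pose.pelvis_height
    pelvis = np.array([0.0, h, _SENSOR_DISTANCE + pose.pelvis_dz])
    sd = np.array(
        [0.0, math.cos(pose.trunk_pitch), -math.sin(pose.trunk_pitch)]
    )
    pos: dict[Joint, np.ndarray] = {Joint.HIP_CENTER: pelvis}
    pos[Joint.SPINE] = pelvis + body.trunk_lower * sd
    pos[Joint.SHOULDER_CENTER] = pos[Joint.SPINE] + body.trunk_upper * sd
    pos[Joint.HEAD] = pos[Joint.SHOULDER_CENTER] + body.neck * sd
    lateral = np.array([1.0, 0.0, 0.0])
    for i, (side, sign) in enumerate((("L", -1.0), ("R", 1.0))):
        sh = pos[Joint.SHOULDER_CENTER] + sign * body.shoulder_half * lateral
        pos[Joint[f"SHOULDER_{side}"]] = sh
        ua = _dir(pose.sh_sag[i], pose.sh_lat[i], sign)
        elbow = sh + body.upper_arm * ua
        fa = _dir(pose.sh_sag[i] + pose.elb[i], pose.sh_lat[i], sign)
        wrist = elbow + body.forearm * fa
        pos[Joint[f"ELBOW_{side}"]] = elbow
        pos[Joint[f"WRIST_{side}"]] = wrist
        pos[Joint[f"HAND_{side}"]] = wrist + body.hand * fa

        hip = pelvis + sign * body.hip_half * lateral
        pos[Joint[f"HIP_{side}"]] = hip
        th = _dir(pose.hip_sag[i], pose.hip_lat[i], sign)
        knee = hip + body.thigh * th
        sh_dir = _dir(pose.hip_sag[i] - pose.knee[i], pose.hip_lat[i], sign)
        ankle = knee + body.shank * sh_dir
        pos[Joint[f"KNEE_{side}"]] = knee
        pos[Joint[f"ANKLE_{side}"]] = ankle
        pos[Joint[f"FOOT_{side}"]] = ankle + body.foot * _dir(_FOOT_SAG, 0.0, sign)
    return SkeletonFrame(timestamp, pos)


# ---------------------------------------------------------------------------
# Activity scripts
# ---------------------------------------------------------------------------

PoseFn = Callable[[BodyModel, float], Pose]


@dataclass(frozen=True)
class ActivityScript:
    """Deterministic kinematics of one activity: (body, phase) -> pose."""

    name: str
    kind: str  # "posture" | "movement"
    duration: float  # seconds per repetition
    uses: frozenset[Extremity]
    laterality: Laterality
    sink: bool
    pose_fn: PoseFn

    @property
    def spec(self) -> ActivitySpec:
        return ActivitySpec(
            name=self.name,
            kind=self.kind,
            extremities=self.uses,
            laterality=self.laterality,
            body_use="global" if self.uses == frozenset(Extremity) else "bounded",
            sink=self.sink,
        )

    def frame(self, body: BodyModel, phase: float, timestamp: float = 0.0) -> SkeletonFrame:
        return build_frame(body, self.pose_fn(body, phase), timestamp)

    def mirrored(self) -> "ActivityScript":
        """The opposite-side script (frame-level mirror of this one)."""
        spec = self.spec.mirrored()  # validates laterality and flips the name

        def mirrored_pose(body: BodyModel, p: float) -> Pose:
            q = self.pose_fn(body, p)
            return replace(
                q,
                sh_sag=q.sh_sag[::-1], sh_lat=q.sh_lat[::-1], elb=q.elb[::-1],
                hip_sag=q.hip_sag[::-1], hip_lat=q.hip_lat[::-1], knee=q.knee[::-1],
            )

        return replace(
            self,
            name=spec.name,
            uses=spec.extremities,
            laterality=spec.laterality,
            pose_fn=mirrored_pose,
        )


def _rise(p: float) -> float:
    """Smooth monotone envelope 0 -> 1 over the repetition."""
    return math.sin(0.5 * math.pi * p)


def _ramp(p: float) -> float:
    """Reach 1 by mid-repetition and hold."""
    return math.sin(0.5 * math.pi * min(2.0 * p, 1.0))


_ARMS = frozenset({Extremity.ARM_L, Extremity.ARM_R})
_LEGS = frozenset({Extremity.LEG_L, Extremity.LEG_R})
_ALL = frozenset(Extremity)

_WALK_CYCLES = 1.75  # ends mid-swing, legs apart
_WALK_SPEED = 0.25  # m/s pelvis drift


def _walk_core(body: BodyModel, theta: float, dz: float) -> Pose:
    a_leg, a_knee, a_arm = math.radians(30), math.radians(50), math.radians(25)
    s = math.sin(theta)
    return Pose(
        hip_sag=(-a_leg * s, a_leg * s),
        knee=(a_knee * max(0.0, -s), a_knee * max(0.0, s)),
        sh_sag=(a_arm * s, -a_arm * s),
        pelvis_dz=dz,
    )


def _stand(body: BodyModel, p: float) -> Pose:
    return Pose()


def _stay_seated(body: BodyModel, p: float) -> Pose:
    half_pi = math.pi / 2
    return Pose(
        hip_sag=(half_pi, half_pi),
        knee=(half_pi, half_pi),
        pelvis_height=body.shank + _ANKLE_HEIGHT,
    )


def _walk(body: BodyModel, p: float) -> Pose:
    return _walk_core(body, 2 * math.pi * _WALK_CYCLES * p, -_WALK_SPEED * p * 2.0)


def _walk_backwards(body: BodyModel, p: float) -> Pose:
    # time-reversed gait (knee flexion now accompanies the backward swing),
    # phase-offset so the repetition ends legs-apart, pelvis drifting away
    theta = 2 * math.pi * _WALK_CYCLES + 0.5 * math.pi - 2 * math.pi * _WALK_CYCLES * p
    return _walk_core(body, theta, _WALK_SPEED * p * 2.0)


def _drink(body: BodyModel, p: float) -> Pose:
    e = _rise(p)
    return Pose(
        sh_sag=(0.0, math.radians(15) * e),
        sh_lat=(0.0, math.radians(10) * e),
        elb=(0.0, math.radians(140) * e),
    )


def _grab_object(body: BodyModel, p: float) -> Pose:
    # straight-arm forward reach toward an object at chest height
    e = _rise(p)
    return Pose(sh_sag=(0.0, math.radians(60) * e))


def _leg_flexion(body: BodyModel, p: float) -> Pose:
    e = _rise(p)
    return Pose(
        knee=(math.radians(100) * e, 0.0),
        trunk_pitch=math.radians(18) * e,
    )


def _leg_circular_swing(body: BodyModel, p: float) -> Pose:
    phi = 2 * math.pi * 0.75 * p  # three quarters of the circle, ends off-center
    a = math.radians(25)
    return Pose(
        hip_sag=(a * math.sin(phi), 0.0),
        hip_lat=(a * (1.0 - math.cos(phi)), 0.0),
        knee=(math.radians(15) * _ramp(p), 0.0),
        trunk_pitch=math.radians(14) * _ramp(p),
    )


ACTIVITIES: dict[str, ActivityScript] = {
    s.name: s
    for s in (
        ActivityScript("Stand", "posture", 2.0, _ALL, Laterality.SYMMETRIC, True, _stand),
        ActivityScript("Stay Seated", "posture", 2.0, _ALL, Laterality.SYMMETRIC, True,
                       _stay_seated),
        ActivityScript("Walk [D]", "movement", 2.0, _ALL, Laterality.D, True, _walk),
        ActivityScript("Walk Backwards [D]", "movement", 2.0, _ALL, Laterality.D, True,
                       _walk_backwards),
        ActivityScript("Drink [D]", "movement", 2.0, frozenset({Extremity.ARM_R}),
                       Laterality.D, False, _drink),
        ActivityScript("Grab Object [D]", "movement", 2.0, frozenset({Extremity.ARM_R}),
                       Laterality.D, False, _grab_object),
        ActivityScript("Leg Flexion [I]", "movement", 2.0, frozenset({Extremity.LEG_L}),
                       Laterality.I, False, _leg_flexion),
        ActivityScript("Leg Circular Swing [I]", "movement", 2.0,
                       frozenset({Extremity.LEG_L}), Laterality.I, False,
                       _leg_circular_swing),
    )
}

ACTIVITY_ORDER: tuple[str, ...] = tuple(ACTIVITIES)
SINK_ACTIVITIES: tuple[str, ...] = tuple(n for n, s in ACTIVITIES.items() if s.sink)
LEG_ACTIVITIES: tuple[str, ...] = tuple(
    n for n, s in ACTIVITIES.items()
    if s.uses and s.uses <= _LEGS
)


def with_balance_sway(script: ActivityScript, sway_amplitude: float) -> ActivityScript:
    """Superimpose an unconscious balance reach of the right arm on a leg script.

    The reach follows the same slow forward arc as the Grab Object movement;
    its peak shoulder angle is ``sway_amplitude`` divided by the arm length.
    Leg kinematics and the label are unchanged. Amplitude 0 returns the
    script unchanged.
    """
    if not script.uses or not script.uses <= _LEGS:
        raise ConfigurationError(
            f"{script.name}: balance sway applies only to leg activities"
        )
    if sway_amplitude == 0.0:
        return script

    def swayed(body: BodyModel, p: float) -> Pose:
        q = script.pose_fn(body, p)
        theta = sway_amplitude / (body.upper_arm + body.forearm)
        return replace(q, sh_sag=(q.sh_sag[0], q.sh_sag[1] + theta * _rise(p)))

    return replace(script, pose_fn=swayed)


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def generate_sequence(
    script: ActivityScript | str,
    body: BodyModel,
    fps: float = DEFAULT_FPS,
    noise: NoiseParams | None = None,
) -> SkeletonSequence:
    """One labeled repetition of an activity: script kinematics plus noise.

    Deterministic given ``noise.seed``; with zero jitter and spike
    probability the output equals the noiseless script exactly.
    """
    if isinstance(script, str):
        try:
            script = ACTIVITIES[script]
        except KeyError:
            raise ConfigurationError(f"unknown activity script {script!r}")
    if fps <= 0:
        raise ValidationError("fps must be positive")
    n = int(round(script.duration * fps)) + 1
    if script.kind == "movement" and n < 2:
        raise ValidationError("movement needs duration*fps >= 2 frames")
    noise = NoiseParams.zero() if noise is None else noise
    rng = np.random.default_rng(noise.seed)
    scale = 1.0
    if noise.exec_sd > 0.0:
        # one execution-amplitude draw per repetition; clipped to stay physical
        scale = float(np.clip(rng.normal(1.0, noise.exec_sd), 0.5, 1.5))

    clean = np.empty((n, len(Joint), 3))
    frames: list[SkeletonFrame] = []
    for i in range(n):
        p = i / (n - 1) if n > 1 else 0.0
        pose = script.pose_fn(body, p)
        if scale != 1.0:
            pose = _scale_pose(pose, scale)
        frame = build_frame(body, pose, timestamp=i / fps)
        for j in Joint:
            clean[i, j.value] = frame.positions[j]
        frames.append(frame)

    rel = np.array([JOINT_RELIABILITY[j] for j in Joint])
    jitter = rng.normal(0.0, 1.0, size=(n, len(Joint), 3)) * (
        noise.jitter_sd * rel[None, :, None]
    )
    # spikes strike joints in motion: speed relative to the pelvis, so a
    # still user never triggers the inference failure mode
    relative = clean - clean[:, Joint.HIP_CENTER.value : Joint.HIP_CENTER.value + 1, :]
    speed = np.zeros((n, len(Joint)))
    if n > 1:
        step = np.linalg.norm(np.diff(relative, axis=0), axis=-1) * fps
        speed[1:] = step
        speed[0] = step[0]
    motion = np.minimum(speed / _SPIKE_SPEED_SCALE, 2.0)
    spike_mask = rng.random(size=(n, len(Joint))) < np.minimum(
        noise.spike_prob * rel * motion, 1.0
    )
    spikes = rng.normal(0.0, noise.spike_sd, size=(n, len(Joint), 3))

    if noise.jitter_sd > 0.0 or noise.spike_prob > 0.0:
        for i in range(n):
            for j in Joint:
                delta = jitter[i, j.value]
                if spike_mask[i, j.value]:
                    delta = delta + spikes[i, j.value]
                if noise.jitter_sd > 0.0 or spike_mask[i, j.value]:
                    frames[i].positions[j] = frames[i].positions[j] + delta
    return SkeletonSequence(frames, fps, label=script.name)


def _scale_pose(pose: Pose, s: float) -> Pose:
    def sc(pair: tuple[float, float]) -> tuple[float, float]:
        return (pair[0] * s, pair[1] * s)

    return replace(
        pose,
        trunk_pitch=pose.trunk_pitch * s,
        sh_sag=sc(pose.sh_sag),
        sh_lat=sc(pose.sh_lat),
        elb=sc(pose.elb),
        hip_sag=sc(pose.hip_sag),
        hip_lat=sc(pose.hip_lat),
        knee=sc(pose.knee),
    )


def sequence_seed(
    master_seed: int, participant_id: str, activity: str, repetition: int
) -> np.random.SeedSequence:
    """One reproducible RNG stream per (participant, activity, repetition)."""
    return np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(
            zlib.crc32(participant_id.encode()),
            zlib.crc32(activity.encode()),
            int(repetition),
        ),
    )


def make_template(
    script: ActivityScript | str,
    body: BodyModel,
    variant: JointSetVariant,
    fps: float = DEFAULT_FPS,
    min_limit: float | None = None,
) -> ActivityTemplate:
    """Zero-noise key sample of an activity for one joint-set variant."""
    if isinstance(script, str):
        script = ACTIVITIES[script]
    seq = generate_sequence(script, body, fps=fps, noise=NoiseParams.zero())
    key_sample: SkeletonFrame | SkeletonSequence
    key_sample = seq.frames[0] if script.kind == "posture" else seq
    import warnings as _warnings

    with _warnings.catch_warnings():
        # sink templates here take their limits from a LimitTable at predict
        # time, not from the template record
        _warnings.simplefilter("ignore")
        return ActivityTemplate(
            name=script.name,
            kind=script.kind,
            key_sample=key_sample,
            relevant_joints=variant_joints(script.spec, variant),
            laterality=script.laterality,
            body_use=script.spec.body_use,
            sink=script.sink,
            min_limit=min_limit,
        )
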