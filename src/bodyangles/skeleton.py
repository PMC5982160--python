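"""Skeleton data model: the 20-joint enumeration, bone topology, frames,
sequences, mirroring, and the CSV/JSON sequence dialects.

Coordinate convention: meters, right-handed, y up, z pointing from the person
toward the sensor (Kinect-like), origin at the sensor. The convention is
recorded in the CSV header so files are self-describing.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    SequenceParseError,
    UnknownJointError,
    ValidationError,
)

__all__ = [
    "Joint",
    "Bone",
    "STANDARD_EDGES",
    "GIRDLE_EDGES",
    "TOPOLOGY",
    "MIRROR_JOINT",
    "SkeletonFrame",
    "SkeletonSequence",
    "bones_induced",
    "mirror_frame",
    "read_sequence",
    "write_sequence",
]


class Joint(Enum):
    """The 20 joints tracked by a Kinect-v1-style skeletal device.

    Enumeration order is proximal-to-distal down the kinematic chains, which
    lets :class:`Bone` canonicalize endpoint order by enum position.
    """

    HIP_CENTER = 0
    SPINE = 1
    SHOULDER_CENTER = 2
    HEAD = 3
    SHOULDER_L = 4
    SHOULDER_R = 5
    ELBOW_L = 6
    ELBOW_R = 7
    WRIST_L = 8
    WRIST_R = 9
    HAND_L = 10
    HAND_R = 11
    HIP_L = 12
    HIP_R = 13
    KNEE_L = 14
    KNEE_R = 15
    ANKLE_L = 16
    ANKLE_R = 17
    FOOT_L = 18
    FOOT_R = 19

    def __repr__(self) -> str:  # compact in error messages and test output
        return self.name


def _mirror_name(name: str) -> str:
    if name.endswith("_L"):
        return name[:-2] + "_R"
    if name.endswith("_R"):
        return name[:-2] + "_L"
    return name


#: Left/right mirror partner of every joint; center-line joints map to themselves.
MIRROR_JOINT: dict[Joint, Joint] = {j: Joint[_mirror_name(j.name)] for j in Joint}


@dataclass(frozen=True)
class Bone:
    """An undirected edge of the skeleton topology.

    Endpoints are canonicalized (proximal = lower enum position) so a bone
    compares and hashes identically regardless of construction order.
    """

    proximal: Joint
    distal: Joint

    def __post_init__(self) -> None:
        if self.proximal is self.distal:
            raise ValidationError(f"bone endpoints must differ: {self.proximal!r}")
        if self.proximal.value > self.distal.value:
            p, d = self.distal, self.proximal
            object.__setattr__(self, "proximal", p)
            object.__setattr__(self, "distal", d)

    @property
    def joints(self) -> frozenset[Joint]:
        return frozenset((self.proximal, self.distal))

    def mirrored(self) -> "Bone":
        return Bone(MIRROR_JOINT[self.proximal], MIRROR_JOINT[self.distal])

    def __repr__(self) -> str:
        return f"{self.proximal.name}-{self.distal.name}"


def _edges(pairs: Iterable[tuple[str, str]]) -> frozenset[Bone]:
    return frozenset(Bone(Joint[a], Joint[b]) for a, b in pairs)


#: The 19 standard Kinect-v1 edges; a tree spanning all 20 joints.
STANDARD_EDGES: frozenset[Bone] = _edges(
    [
        ("HIP_CENTER", "SPINE"),
        ("SPINE", "SHOULDER_CENTER"),
        ("SHOULDER_CENTER", "HEAD"),
        ("SHOULDER_CENTER", "SHOULDER_L"),
        ("SHOULDER_CENTER", "SHOULDER_R"),
        ("SHOULDER_L", "ELBOW_L"),
        ("SHOULDER_R", "ELBOW_R"),
        ("ELBOW_L", "WRIST_L"),
        ("ELBOW_R", "WRIST_R"),
        ("WRIST_L", "HAND_L"),
        ("WRIST_R", "HAND_R"),
        ("HIP_CENTER", "HIP_L"),
        ("HIP_CENTER", "HIP_R"),
        ("HIP_L", "KNEE_L"),
        ("HIP_R", "KNEE_R"),
        ("KNEE_L", "ANKLE_L"),
        ("KNEE_R", "ANKLE_R"),
        ("ANKLE_L", "FOOT_L"),
        ("ANKLE_R", "FOOT_R"),
    ]
)

#: Cross-body girdle edges. They give shoulder/hip-only joint sets a usable
#: reference bone even when no trunk joint is selected.
GIRDLE_EDGES: frozenset[Bone] = _edges(
    [("SHOULDER_L", "SHOULDER_R"), ("HIP_L", "HIP_R")]
)

#: Full working topology: 21 bones.
TOPOLOGY: frozenset[Bone] = STANDARD_EDGES | GIRDLE_EDGES

#: Stable bone ordering used for array layouts.
BONE_ORDER: tuple[Bone, ...] = tuple(
    sorted(TOPOLOGY, key=lambda b: (b.proximal.value, b.distal.value))
)
BONE_INDEX: dict[Bone, int] = {b: i for i, b in enumerate(BONE_ORDER)}


def bones_induced(
    joints: Iterable[Joint], topology: frozenset[Bone] = TOPOLOGY
) -> frozenset[Bone]:
    """Bones of ``topology`` with both endpoints in ``joints``.

    Relevant bones derive from relevant joints: selecting a joint subset for
    an activity selects exactly the edges it spans. Empty input yields the
    empty set (downstream similarity operations reject empty bone sets).
    """
    js = frozenset(joints)
    return frozenset(b for b in topology if b.joints <= js)


@dataclass
class SkeletonFrame:
    """One timestamped observation: joint name -> 3-D position in meters."""

    timestamp: float
    positions: dict[Joint, np.ndarray]

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValidationError(f"negative timestamp {self.timestamp}")
        clean: dict[Joint, np.ndarray] = {}
        for j, p in self.positions.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,):
                raise ValidationError(f"position of {j!r} is not a 3-vector")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite coordinates for {j!r}")
            clean[j] = arr
        self.positions = clean

    def validate_joints(self, required: Iterable[Joint] | None = None) -> None:
        """Check that all required joints are present (default: all 20)."""
        req = set(Joint) if required is None else set(required)
        missing = req - set(self.positions)
        if missing:
            names = ", ".join(sorted(j.name for j in missing))
            raise ValidationError(f"frame at t={self.timestamp} missing joints: {names}")

    def translated(self, offset) -> "SkeletonFrame":
        off = np.asarray(offset, dtype=float)
        return SkeletonFrame(
            self.timestamp, {j: p + off for j, p in self.positions.items()}
        )

    def allclose(self, other: "SkeletonFrame", atol: float = 1e-12) -> bool:
        if set(self.positions) != set(other.positions):
            return False
        return all(
            np.allclose(self.positions[j], other.positions[j], atol=atol)
            for j in self.positions
        )


def mirror_frame(frame: SkeletonFrame) -> SkeletonFrame:
    """Swap left/right joints and reflect x about the body midline.

    The midline is the x-coordinate of HIP_CENTER, so mirroring is an
    involution and preserves every inter-joint distance. Center-line joints
    keep their labels, with x reflected like all others.
    """
    if Joint.HIP_CENTER not in frame.positions:
        raise ValidationError("mirroring requires HIP_CENTER to define the midline")
    x0 = frame.positions[Joint.HIP_CENTER][0]
    out: dict[Joint, np.ndarray] = {}
    for j, p in frame.positions.items():
        q = p.copy()
        q[0] = 2.0 * x0 - q[0]
        out[MIRROR_JOINT[j]] = q
    return SkeletonFrame(frame.timestamp, out)


@dataclass
class SkeletonSequence:
    """An ordered run of frames with a nominal frame rate and optional label."""

    frames: list[SkeletonFrame]
    fps: float
    label: str | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Elapsed time between first and last frame, in seconds."""
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].timestamp - self.frames[0].timestamp

    def check_fps_consistency(self, rel_tol: float = 0.01) -> None:
        """Verify the stored fps against frame spacing (within ``rel_tol``)."""
        if len(self.frames) < 2:
            return
        measured = (len(self.frames) - 1) / self.duration
        if abs(measured - self.fps) > rel_tol * self.fps:
            raise ValidationError(
                f"declared fps {self.fps} inconsistent with measured {measured:.3f}"
            )

    def joint_array(self) -> np.ndarray:
        """(n_frames, 20, 3) position array; requires complete frames. Cached."""
        arr = self._cache.get("joints")
        if arr is None:
            arr = np.empty((len(self.frames), len(Joint), 3))
            for i, f in enumerate(self.frames):
                f.validate_joints()
                for j in Joint:
                    arr[i, j.value] = f.positions[j]
            self._cache["joints"] = arr
        return arr

    def tail(self, duration: float) -> "SkeletonSequence":
        """Trailing window of approximately ``duration`` seconds."""
        t_end = self.frames[-1].timestamp
        frames = [f for f in self.frames if f.timestamp >= t_end - duration - 1e-9]
        return SkeletonSequence(frames, self.fps, self.label)


# ---------------------------------------------------------------------------
# Sequence file dialects
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("frame_index", "timestamp", "joint", "x", "y", "z")


def write_sequence(seq: SkeletonSequence, path: str | Path, format: str = "csv") -> None:
    """Write ``seq`` so that :func:`read_sequence` inverts it exactly."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="\n", encoding="utf-8") as fh:
            fh.write(f"#fps={seq.fps!r}\n")
            fh.write("#coords=meters\n")
            if seq.label is not None:
                fh.write(f"#label={seq.label}\n")
            fh.write(",".join(_CSV_FIELDS) + "\n")
            for i, frame in enumerate(seq.frames):
                for j in Joint:
                    if j not in frame.positions:
                        continue
                    x, y, z = (float(v) for v in frame.positions[j])
                    fh.write(
                        f"{i},{float(frame.timestamp)!r},{j.name},{x!r},{y!r},{z!r}\n"
                    )
    elif format == "json":
        doc = {
            "fps": seq.fps,
            "label": seq.label,
            "frames": [
                {
                    "t": f.timestamp,
                    "positions": {
                        j.name: [float(v) for v in f.positions[j]]
                        for j in Joint
                        if j in f.positions
                    },
                }
                for f in seq.frames
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _parse_float(text: str, what: str, line: int, path: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise SequenceParseError(f"malformed {what} {text!r}", line=line, path=path)
    if not math.isfinite(v):
        raise SequenceParseError(f"non-finite {what} {text!r}", line=line, path=path)
    return v


def read_sequence(path: str | Path, format: str | None = None) -> SkeletonSequence:
    """Read a sequence in the CSV or JSON dialect.

    ``format`` defaults to the file suffix. Malformed rows, unknown joint
    names and non-increasing timestamps raise parse errors naming the line.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        return _read_json(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> SkeletonSequence:
    fps: float | None = None
    label: str | None = None
    sp = str(path)
    frames: list[SkeletonFrame] = []
    current_index: int | None = None
    current_t: float | None = None
    current_pos: dict[Joint, np.ndarray] = {}

    def flush() -> None:
        nonlocal current_pos, current_t
        if current_t is not None:
            frames.append(SkeletonFrame(current_t, current_pos))
        current_pos = {}

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "fps":
                    fps = _parse_float(val, "fps", lineno, sp)
                elif key == "label":
                    label = val
                continue
            if line.startswith("frame_index,"):
                continue  # column header
            parts = line.split(",")
            if len(parts) != 6:
                raise SequenceParseError(
                    f"expected 6 fields, got {len(parts)}", line=lineno, path=sp
                )
            idx_s, t_s, joint_s, x_s, y_s, z_s = parts
            try:
                idx = int(idx_s)
            except ValueError:
                raise SequenceParseError(
                    f"malformed frame index {idx_s!r}", line=lineno, path=sp
                )
            try:
                joint = Joint[joint_s]
            except KeyError:
                raise UnknownJointError(
                    f"unknown joint name {joint_s!r}", line=lineno, path=sp
                )
            t = _parse_float(t_s, "timestamp", lineno, sp)
            pos = np.array(
                [
                    _parse_float(x_s, "x", lineno, sp),
                    _parse_float(y_s, "y", lineno, sp),
                    _parse_float(z_s, "z", lineno, sp),
                ]
            )
            if idx != current_index:
                if current_index is not None and idx <= current_index:
                    raise SequenceParseError(
                        f"frame index {idx} does not increase", line=lineno, path=sp
                    )
                if current_t is not None and t <= current_t:
                    raise SequenceParseError(
                        f"timestamp {t} does not increase", line=lineno, path=sp
                    )
                flush()
                current_index, current_t = idx, t
            current_pos[joint] = pos
        flush()
    if fps is None:
        raise SequenceParseError("missing #fps header", path=sp)
    return SkeletonSequence(frames, fps, label)


def _read_json(path: Path) -> SkeletonSequence:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SequenceParseError(
                f"invalid JSON: {exc.msg}", line=exc.lineno, path=str(path)
            )
    frames = []
    for k, fr in enumerate(doc.get("frames", [])):
        pos: dict[Joint, np.ndarray] = {}
        for name, xyz in fr["positions"].items():
            try:
                joint = Joint[name]
            except KeyError:
                raise UnknownJointError(f"unknown joint name {name!r} in frame {k}",
                                        path=str(path))
            pos[joint] = np.asarray(xyz, dtype=float)
        frames.append(SkeletonFrame(float(fr["t"]), pos))
    try:
        return SkeletonSequence(frames, float(doc["fps"]), doc.get("label"))
    except ValidationError as exc:
        raise SequenceParseError(str(exc), path=str(path))
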