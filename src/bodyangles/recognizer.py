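"""Activity templates, joint-set variants, and gated prediction.

Each activity is represented by a single key sample (a posture frame or a
movement sequence) plus the set of joints relevant to it. Three systematic
joint-set variants are supported for an activity that uses a declared set of
extremities:

* **vB** — joints of the used extremity chain(s), excluding hands and feet,
  plus both shoulders and both hips (the girdle joints belong to both trunk
  and extremities);
* **vT** — vB plus the trunk joints (HIP_CENTER, SPINE, SHOULDER_CENTER);
* **vC** — all 20 joints except hands, feet and head (15 joints).

Prediction scores every registered template against the observation, removes
("gates") any activity whose score falls below its minimum limit of
prediction, and takes the argmax of the remainder; if even the best survivor
falls below the global limit the observation is labelled UNKNOWN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np

from .calibration import LimitTable
from .errors import (
    ConfigurationError,
    NoPredictionError,
    SpeedMismatchError,
    ValidationError,
)
from .similarity import (
    DURATION_TOLERANCE,
    SimilarityReport,
    body_similarity,
    sequence_similarity,
)
from .skeleton import (
    MIRROR_JOINT,
    TOPOLOGY,
    Bone,
    Joint,
    SkeletonFrame,
    SkeletonSequence,
    bones_induced,
    mirror_frame,
    read_sequence,
    write_sequence,
)

__all__ = [
    "Laterality",
    "Extremity",
    "ActivitySpec",
    "JointSetVariant",
    "ActivityTemplate",
    "Prediction",
    "variant_joints",
    "mirror_template",
    "score_all",
    "decide",
    "predict",
    "UNKNOWN",
]

UNKNOWN = "UNKNOWN"

#: Joints never used by any variant: hand and foot tracking is too unstable.
_EXCLUDED_DISTAL = {Joint.HAND_L, Joint.HAND_R, Joint.FOOT_L, Joint.FOOT_R}

#: The girdle joints; union points between trunk and extremities, always in vB.
_GIRDLE = {Joint.SHOULDER_L, Joint.SHOULDER_R, Joint.HIP_L, Joint.HIP_R}

_TRUNK = {Joint.HIP_CENTER, Joint.SPINE, Joint.SHOULDER_CENTER}

#: vC: all joints except hands, feet and head.
_VC_JOINTS = frozenset(set(Joint) - _EXCLUDED_DISTAL - {Joint.HEAD})


class Laterality(Enum):
    D = "D"  # right side
    I = "I"  # left side
    SYMMETRIC = "symmetric"


class Extremity(Enum):
    """A limb chain, shoulder/hip to hand/foot."""

    ARM_L = ("SHOULDER_L", "ELBOW_L", "WRIST_L", "HAND_L")
    ARM_R = ("SHOULDER_R", "ELBOW_R", "WRIST_R", "HAND_R")
    LEG_L = ("HIP_L", "KNEE_L", "ANKLE_L", "FOOT_L")
    LEG_R = ("HIP_R", "KNEE_R", "ANKLE_R", "FOOT_R")

    @property
    def joints(self) -> frozenset[Joint]:
        return frozenset(Joint[n] for n in self.value)

    def mirrored(self) -> "Extremity":
        name = self.name[:-1] + ("R" if self.name.endswith("L") else "L")
        return Extremity[name]


ALL_EXTREMITIES = frozenset(Extremity)


class JointSetVariant(Enum):
    vB = "vB"
    vT = "vT"
    vC = "vC"


@dataclass(frozen=True)
class ActivitySpec:
    """What an activity uses: its extremities, laterality and body use."""

    name: str
    kind: str  # "posture" | "movement"
    extremities: frozenset[Extremity]
    laterality: Laterality = Laterality.SYMMETRIC
    body_use: str = "bounded"  # "global" | "bounded"
    sink: bool = False

    def mirrored(self) -> "ActivitySpec":
        if self.laterality is Laterality.SYMMETRIC:
            raise ConfigurationError(f"{self.name}: symmetric activity has no mirror")
        return replace(
            self,
            name=_flip_name(self.name),
            extremities=frozenset(e.mirrored() for e in self.extremities),
            laterality=(
                Laterality.I if self.laterality is Laterality.D else Laterality.D
            ),
        )


def _flip_name(name: str) -> str:
    if name.endswith("[D]"):
        return name[:-3] + "[I]"
    if name.endswith("[I]"):
        return name[:-3] + "[D]"
    return name


def variant_joints(spec: ActivitySpec, variant: JointSetVariant) -> frozenset[Joint]:
    """The joint set an activity uses under a joint-set variant."""
    if variant is JointSetVariant.vC:
        return _VC_JOINTS
    chain: set[Joint] = set()
    for ext in spec.extremities:
        chain |= ext.joints
    vb = (chain - _EXCLUDED_DISTAL) | _GIRDLE
    if variant is JointSetVariant.vB:
        return frozenset(vb)
    if variant is JointSetVariant.vT:
        return frozenset(vb | _TRUNK)
    raise ConfigurationError(f"unknown variant {variant!r}")


@dataclass
class ActivityTemplate:
    """A single key sample of an activity plus its relevant joints.

    ``key_sample`` is a :class:`SkeletonFrame` for postures and a
    :class:`SkeletonSequence` for movements. ``min_limit`` is the optional
    per-activity minimum limit of prediction (sink activities should have
    one; a template-level limit overrides none but is itself overridden by a
    :class:`LimitTable` entry at prediction time).
    """

    name: str
    kind: str  # "posture" | "movement"
    key_sample: SkeletonFrame | SkeletonSequence
    relevant_joints: frozenset[Joint]
    laterality: Laterality = Laterality.SYMMETRIC
    body_use: str = "bounded"
    sink: bool = False
    min_limit: float | None = None

    def __post_init__(self) -> None:
        self.relevant_joints = frozenset(self.relevant_joints)
        if not self.relevant_bones:
            raise ConfigurationError(
                f"{self.name}: relevant joints induce no bones"
            )
        if self.kind == "movement":
            if not isinstance(self.key_sample, SkeletonSequence) or len(self.key_sample) < 2:
                raise ValidationError(
                    f"{self.name}: movement key sample needs at least 2 frames"
                )
        elif self.kind == "posture":
            if not isinstance(self.key_sample, SkeletonFrame):
                raise ValidationError(f"{self.name}: posture key sample must be a frame")
        else:
            raise ValidationError(f"{self.name}: kind must be posture or movement")
        if self.sink and self.min_limit is None:
            warnings.warn(
                f"sink activity {self.name!r} has no minimum limit of prediction",
                stacklevel=2,
            )

    @property
    def relevant_bones(self) -> frozenset[Bone]:
        return bones_induced(self.relevant_joints, TOPOLOGY)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        if isinstance(self.key_sample, SkeletonFrame):
            sample = {
                "t": self.key_sample.timestamp,
                "positions": {
                    j.name: [float(v) for v in p]
                    for j, p in self.key_sample.positions.items()
                },
            }
        else:
            sample = {
                "fps": self.key_sample.fps,
                "label": self.key_sample.label,
                "frames": [
                    {
                        "t": f.timestamp,
                        "positions": {
                            j.name: [float(v) for v in p] for j, p in f.positions.items()
                        },
                    }
                    for f in self.key_sample.frames
                ],
            }
        doc = {
            "name": self.name,
            "kind": self.kind,
            "laterality": self.laterality.value,
            "body_use": self.body_use,
            "sink": self.sink,
            "min_limit": self.min_limit,
            "relevant_joints": sorted(j.name for j in self.relevant_joints),
            "key_sample": sample,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ActivityTemplate":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        sample_doc = doc["key_sample"]

        def frame(fr: Mapping) -> SkeletonFrame:
            return SkeletonFrame(
                float(fr["t"]),
                {Joint[n]: np.asarray(p, dtype=float) for n, p in fr["positions"].items()},
            )

        if doc["kind"] == "posture":
            sample: SkeletonFrame | SkeletonSequence = frame(sample_doc)
        else:
            sample = SkeletonSequence(
                [frame(fr) for fr in sample_doc["frames"]],
                float(sample_doc["fps"]),
                sample_doc.get("label"),
            )
        return cls(
            name=doc["name"],
            kind=doc["kind"],
            key_sample=sample,
            relevant_joints=frozenset(Joint[n] for n in doc["relevant_joints"]),
            laterality=Laterality(doc.get("laterality", "symmetric")),
            body_use=doc.get("body_use", "bounded"),
            sink=bool(doc.get("sink", False)),
            min_limit=doc.get("min_limit"),
        )


def mirror_template(template: ActivityTemplate) -> ActivityTemplate:
    """The opposite-side version of an asymmetric activity's template."""
    if template.laterality is Laterality.SYMMETRIC:
        raise ConfigurationError(
            f"{template.name}: symmetric template has no mirrored version"
        )
    if isinstance(template.key_sample, SkeletonFrame):
        sample: SkeletonFrame | SkeletonSequence = mirror_frame(template.key_sample)
    else:
        sample = SkeletonSequence(
            [mirror_frame(f) for f in template.key_sample.frames],
            template.key_sample.fps,
            _flip_name(template.key_sample.label) if template.key_sample.label else None,
        )
    return ActivityTemplate(
        name=_flip_name(template.name),
        kind=template.kind,
        key_sample=sample,
        relevant_joints=frozenset(MIRROR_JOINT[j] for j in template.relevant_joints),
        laterality=(
            Laterality.I if template.laterality is Laterality.D else Laterality.D
        ),
        body_use=template.body_use,
        sink=template.sink,
        min_limit=template.min_limit,
    )


@dataclass
class Prediction:
    """Outcome of one decision instant."""

    label: str  # an activity name or UNKNOWN
    scores: dict[str, float]
    gated: frozenset[str]
    reports: dict[str, SimilarityReport] = field(default_factory=dict)
    unscorable: dict[str, str] = field(default_factory=dict)


def score_all(
    observation: SkeletonSequence,
    templates: Sequence[ActivityTemplate],
    duration_tolerance: float = DURATION_TOLERANCE,
) -> tuple[dict[str, SimilarityReport], dict[str, str]]:
    """Score every template against the observation.

    Posture templates are scored on the observation's latest frame; movement
    templates on the trailing window matching the template's duration.
    Per-template validation failures are recorded (not fatal) and returned in
    the second mapping.
    """
    reports: dict[str, SimilarityReport] = {}
    unscorable: dict[str, str] = {}
    windows: dict[float, SkeletonSequence] = {}
    for t in templates:
        try:
            bones = t.relevant_bones
            if isinstance(t.key_sample, SkeletonFrame):
                rep = body_similarity(
                    observation.frames[-1], t.key_sample, bones, template_name=t.name
                )
            else:
                key = round(t.key_sample.duration, 9)
                window = windows.get(key)
                if window is None:
                    window = observation.tail(t.key_sample.duration)
                    windows[key] = window
                sim = sequence_similarity(
                    window, t.key_sample, bones, duration_tolerance
                )
                rep = SimilarityReport(t.name, {}, sim)
            reports[t.name] = rep
        except (ValidationError, SpeedMismatchError, ConfigurationError) as exc:
            unscorable[t.name] = str(exc)
    return reports, unscorable


def decide(
    scores: Mapping[str, float],
    limits: LimitTable | None,
    order: Sequence[str],
) -> tuple[str, frozenset[str]]:
    """Apply gating and argmax to a score map.

    ``order`` is the template registration order, used as the deterministic
    tie-break (first registered wins an exact tie). Returns the label (or
    UNKNOWN) and the set of gated activities.
    """
    gated = set()
    if limits is not None:
        for name, s in scores.items():
            lim = limits.get(name)
            if lim is not None and s < lim:
                gated.add(name)
    eligible = [n for n in order if n in scores and n not in gated]
    if not eligible:
        return UNKNOWN, frozenset(gated)
    best = max(eligible, key=lambda n: scores[n])
    global_limit = limits.global_limit if limits is not None else 0.0
    if scores[best] < global_limit:
        return UNKNOWN, frozenset(gated)
    return best, frozenset(gated)


def predict(
    observation: SkeletonSequence,
    templates: Sequence[ActivityTemplate],
    limits: LimitTable | None = None,
    duration_tolerance: float = DURATION_TOLERANCE,
    with_reports: bool = False,
) -> Prediction:
    """Classify an observation against the registered templates.

    Template-level ``min_limit`` values act as defaults; entries in
    ``limits.per_activity`` override them.
    """
    if not templates:
        raise NoPredictionError("no templates registered")
    reports, unscorable = score_all(observation, templates, duration_tolerance)
    if not reports:
        raise NoPredictionError(
            "no template could be scored: "
            + "; ".join(f"{k}: {v}" for k, v in unscorable.items())
        )
    scores = {name: rep.body_similarity for name, rep in reports.items()}
    merged = LimitTable(
        {t.name: t.min_limit for t in templates if t.min_limit is not None},
        limits.global_limit if limits is not None else 0.0,
    )
    if limits is not None:
        merged.per_activity.update(limits.per_activity)
    label, gated = decide(scores, merged, [t.name for t in templates])
    return Prediction(
        label=label,
        scores=scores,
        gated=gated,
        reports=reports if with_reports else {},
        unscorable=unscorable,
    )
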