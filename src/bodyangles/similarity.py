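"""Bone-angle similarity: the core metric of the recognizer.

A bone's feature is the unit direction of the segment between its two joints.
Two bones are compared by the 3-D angle between their directions, mapped
linearly to a percent: 100 * (1 - theta/180deg). A body similarity is the
unweighted arithmetic mean over an activity's relevant bones, so with n
relevant bones each bone contributes with weight 1/n — fewer relevant bones
means each has greater influence on the final score. Irrelevant joints never
enter the computation, which is what lets one key sample cover an activity
independently of the rest of the body.

Because only differences between joint positions are used, every similarity
is invariant under translation of the whole skeleton. No rotation about the
vertical axis is normalized away: samples are assumed recorded facing the
sensor, as Kinect usage implies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateBoneError, SpeedMismatchError, ValidationError
from .skeleton import BONE_INDEX, BONE_ORDER, Bone, Joint, SkeletonFrame, SkeletonSequence

__all__ = [
    "BoneDirection",
    "SimilarityReport",
    "bone_direction",
    "bone_similarity",
    "body_similarity",
    "sequence_similarity",
    "DEGENERATE_LENGTH",
    "DURATION_TOLERANCE",
]

#: Bones shorter than this (in meters) have no defined direction.
DEGENERATE_LENGTH = 1e-6

#: Default relative tolerance on window vs template duration.
DURATION_TOLERANCE = 0.2


@dataclass(frozen=True)
class BoneDirection:
    """Unit vector from a bone's proximal to its distal joint."""

    bone: Bone
    unit_vector: np.ndarray


@dataclass
class SimilarityReport:
    """Per-bone similarities and their mean for one observation vs one template."""

    template_name: str
    bone_sims: dict[Bone, float]
    body_similarity: float

    def to_dict(self) -> dict:
        return {
            "template": self.template_name,
            "body_similarity": round(self.body_similarity, 2),
            "bone_similarities": {
                repr(b): round(s, 2) for b, s in sorted(
                    self.bone_sims.items(), key=lambda kv: repr(kv[0])
                )
            },
        }


def bone_direction(frame: SkeletonFrame, bone: Bone) -> BoneDirection:
    """Normalized proximal-to-distal direction of ``bone`` in ``frame``."""
    for j in (bone.proximal, bone.distal):
        if j not in frame.positions:
            raise ValidationError(f"joint {j!r} missing from frame at t={frame.timestamp}")
    vec = frame.positions[bone.distal] - frame.positions[bone.proximal]
    norm = float(np.linalg.norm(vec))
    if norm < DEGENERATE_LENGTH:
        raise DegenerateBoneError(f"bone {bone!r} endpoints coincide (length {norm:.2e} m)")
    return BoneDirection(bone, vec / norm)


def _angle_to_percent(cos_theta) -> np.ndarray:
    theta = np.arccos(np.clip(cos_theta, -1.0, 1.0))
    return 100.0 * (1.0 - theta / np.pi)


def bone_similarity(dir_a: BoneDirection, dir_b: BoneDirection) -> float:
    """Percent similarity between two directions of the same bone.

    100 for identical directions, 50 for perpendicular, 0 for antiparallel;
    symmetric in its arguments.
    """
    cos = float(np.dot(dir_a.unit_vector, dir_b.unit_vector))
    return float(_angle_to_percent(cos))


def body_similarity(
    frame: SkeletonFrame,
    template_frame: SkeletonFrame,
    relevant_bones: Iterable[Bone],
    template_name: str = "",
) -> SimilarityReport:
    """Mean bone similarity over ``relevant_bones`` between two frames."""
    bones = sorted(set(relevant_bones), key=lambda b: BONE_INDEX.get(b, -1))
    if not bones:
        raise ConfigurationError("relevant bone set is empty")
    sims = {b: bone_similarity(bone_direction(frame, b), bone_direction(template_frame, b))
            for b in bones}
    return SimilarityReport(
        template_name=template_name,
        bone_sims=sims,
        body_similarity=float(np.mean(list(sims.values()))),
    )


# ---------------------------------------------------------------------------
# Vectorized internals used for sequence scoring
# ---------------------------------------------------------------------------

_PROX = np.array([b.proximal.value for b in BONE_ORDER])
_DIST = np.array([b.distal.value for b in BONE_ORDER])


def _edge_directions(seq: SkeletonSequence) -> np.ndarray:
    """(n_frames, 21, 3) unit directions of all topology bones. Cached."""
    dirs = seq._cache.get("edge_dirs")
    if dirs is None:
        joints = seq.joint_array()
        vec = joints[:, _DIST, :] - joints[:, _PROX, :]
        norm = np.linalg.norm(vec, axis=-1, keepdims=True)
        if np.any(norm < DEGENERATE_LENGTH):
            bad = np.argwhere(norm[..., 0] < DEGENERATE_LENGTH)[0]
            raise DegenerateBoneError(
                f"bone {BONE_ORDER[bad[1]]!r} degenerate in frame {bad[0]}"
            )
        dirs = vec / norm
        seq._cache["edge_dirs"] = dirs
    return dirs


def resample_indices(n_window: int, n_template: int) -> np.ndarray:
    """Nearest-frame indices mapping a template's frame grid onto the window."""
    if n_template == 1:
        return np.array([n_window - 1])
    return np.rint(np.linspace(0.0, n_window - 1, n_template)).astype(int)


def sequence_similarity(
    window: SkeletonSequence,
    template: SkeletonSequence,
    relevant_bones: Iterable[Bone],
    duration_tolerance: float = DURATION_TOLERANCE,
) -> float:
    """Frame-synchronous similarity of a window against a movement template.

    The window is uniformly resampled (nearest frame) onto the template's
    frame count; the result is the mean over template frames of the body
    similarity between paired frames. The window's duration must match the
    template's within ``duration_tolerance`` (movements are performed at the
    template's speed; there is no time warping).
    """
    bones = sorted(set(relevant_bones), key=lambda b: BONE_INDEX.get(b, -1))
    if not bones:
        raise ConfigurationError("relevant bone set is empty")
    if len(template) < 2:
        raise ValidationError("movement template needs at least 2 frames")
    dt, dw = template.duration, window.duration
    if abs(dw - dt) > duration_tolerance * dt + 1e-9:
        raise SpeedMismatchError(
            f"window duration {dw:.3f}s outside ±{duration_tolerance:.0%} "
            f"of template duration {dt:.3f}s"
        )
    cols = np.array([BONE_INDEX[b] for b in bones])
    tdirs = _edge_directions(template)[:, cols, :]
    wdirs = _edge_directions(window)[resample_indices(len(window), len(template))][:, cols, :]
    cos = np.einsum("fbk,fbk->fb", tdirs, wdirs)
    return float(np.mean(_angle_to_percent(cos)))
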