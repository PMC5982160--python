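"""Bone-angle similarity: closed forms, oracle equivalence, and invariances."""

import math

import numpy as np
import pytest

from bodyangles.errors import (
    ConfigurationError,
    DegenerateBoneError,
    SpeedMismatchError,
    ValidationError,
)
from bodyangles.similarity import (
    body_similarity,
    bone_direction,
    bone_similarity,
    resample_indices,
    sequence_similarity,
)
from bodyangles.skeleton import (
    TOPOLOGY,
    Bone,
    Joint,
    SkeletonFrame,
    SkeletonSequence,
    bones_induced,
)

from conftest import random_frame, random_sequence

UPPER_ARM_R = Bone(Joint.SHOULDER_R, Joint.ELBOW_R)
FOREARM_R = Bone(Joint.ELBOW_R, Joint.WRIST_R)


def brute_force_body_similarity(frame, template, bones):
    """Independent oracle: explicit loop, mean of per-bone similarities."""
    total = 0.0
    for bone in bones:
        u = bone_direction(frame, bone).unit_vector
        v = bone_direction(template, bone).unit_vector
        theta = math.acos(max(-1.0, min(1.0, float(np.dot(u, v)))))
        total += 100.0 * (1.0 - theta / math.pi)
    return total / len(bones)


class TestBoneDirection:
    def test_axis_aligned_example(self):
        frame = SkeletonFrame(
            0.0,
            {
                Joint.SHOULDER_R: np.array([0.0, 1.0, 0.0]),
                Joint.ELBOW_R: np.array([0.0, 0.7, 0.0]),
            },
        )
        d = bone_direction(frame, UPPER_ARM_R)
        assert d.unit_vector == pytest.approx([0.0, -1.0, 0.0])

    def test_hand_normalization(self, rng):
        frame = random_frame(rng)
        d = bone_direction(frame, FOREARM_R)
        vec = frame.positions[Joint.WRIST_R] - frame.positions[Joint.ELBOW_R]
        assert d.unit_vector == pytest.approx(vec / np.linalg.norm(vec), abs=1e-12)
        assert np.linalg.norm(d.unit_vector) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_endpoints_raise(self):
        frame = SkeletonFrame(
            0.0,
            {Joint.SHOULDER_R: np.zeros(3), Joint.ELBOW_R: np.full(3, 1e-9)},
        )
        with pytest.raises(DegenerateBoneError):
            bone_direction(frame, UPPER_ARM_R)

    def test_missing_joint_names_the_joint(self, rng):
        frame = random_frame(rng)
        del frame.positions[Joint.ELBOW_R]
        with pytest.raises(ValidationError, match="ELBOW_R"):
            bone_direction(frame, UPPER_ARM_R)


class TestBoneSimilarity:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 0, 0), (1, 0, 0), 100.0),
            ((1, 0, 0), (-1, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 50.0),
            ((1, 0, 0), (0, 0, -1), 50.0),
        ],
    )
    def test_closed_forms(self, u, v, expected):
        frame = lambda p, q: SkeletonFrame(
            0.0, {Joint.SHOULDER_R: np.array(p, float), Joint.ELBOW_R: np.array(q, float)}
        )
        da = bone_direction(frame((0, 0, 0), u), UPPER_ARM_R)
        db = bone_direction(frame((0, 0, 0), v), UPPER_ARM_R)
        assert bone_similarity(da, db) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            fa, fb = random_frame(rng), random_frame(rng)
            da = bone_direction(fa, FOREARM_R)
            db = bone_direction(fb, FOREARM_R)
            s = bone_similarity(da, db)
            assert 0.0 <= s <= 100.0
            assert bone_similarity(db, da) == pytest.approx(s, abs=1e-12)

    def test_equals_100_only_for_identical_directions(self, rng):
        fa, fb = random_frame(rng), random_frame(rng)
        da = bone_direction(fa, FOREARM_R)
        db = bone_direction(fb, FOREARM_R)
        assert bone_similarity(da, da) == 100.0
        if not np.allclose(da.unit_vector, db.unit_vector):
            assert bone_similarity(da, db) < 100.0


class TestBodySimilarity:
    def test_template_vs_itself_is_100(self, rng):
        frame = random_frame(rng)
        report = body_similarity(frame, frame, TOPOLOGY)
        # arccos near 1.0 carries ~1e-7 float error; exact zero angle is not
        # representable after normalization round trips
        assert report.body_similarity == pytest.approx(100.0, abs=1e-5)

    def test_mean_of_bone_similarities(self):
        # two bones engineered to score exactly 100 and 0
        base = {
            Joint.SHOULDER_R: np.array([0.0, 0.0, 0.0]),
            Joint.ELBOW_R: np.array([0.0, -1.0, 0.0]),
            Joint.WRIST_R: np.array([0.0, -2.0, 0.0]),
        }
        other = {
            Joint.SHOULDER_R: np.array([0.0, 0.0, 0.0]),
            Joint.ELBOW_R: np.array([0.0, -1.0, 0.0]),  # same upper arm: 100
            Joint.WRIST_R: np.array([0.0, 0.0, 0.0]),  # reversed forearm: 0
        }
        report = body_similarity(
            SkeletonFrame(0.0, other), SkeletonFrame(0.0, base),
            {UPPER_ARM_R, FOREARM_R},
        )
        assert report.bone_sims[UPPER_ARM_R] == pytest.approx(100.0)
        assert report.bone_sims[FOREARM_R] == pytest.approx(0.0)
        assert report.body_similarity == pytest.approx(50.0)

    def test_matches_brute_force_oracle(self, rng):
        bones = bones_induced(set(Joint))
        for _ in range(100):
            fa, fb = random_frame(rng), random_frame(rng)
            report = body_similarity(fa, fb, bones)
            assert report.body_similarity == pytest.approx(
                brute_force_body_similarity(fa, fb, bones), abs=1e-9
            )
            assert set(report.bone_sims) == set(bones)

    def test_empty_bone_set_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            body_similarity(random_frame(rng), random_frame(rng), set())

    def test_translation_invariance(self, rng):
        bones = bones_induced(set(Joint))
        fa, fb = random_frame(rng), random_frame(rng)
        base = body_similarity(fa, fb, bones).body_similarity
        shifted = body_similarity(
            fa.translated([1.3, -0.7, 2.1]), fb.translated([-5.0, 0.1, 0.4]), bones
        ).body_similarity
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_irrelevant_joint_invariance(self, rng):
        bones = bones_induced({Joint.SHOULDER_R, Joint.ELBOW_R, Joint.WRIST_R})
        fa, fb = random_frame(rng), random_frame(rng)
        base = body_similarity(fa, fb, bones).body_similarity
        for j in (Joint.HEAD, Joint.KNEE_L, Joint.HAND_R, Joint.HIP_CENTER):
            fa.positions[j] = rng.uniform(-5, 5, 3)
        assert body_similarity(fa, fb, bones).body_similarity == pytest.approx(
            base, abs=1e-12
        )

    def test_influence_scaling_one_bone_changes_mean_by_delta_over_n(self, rng):
        bones = sorted(
            bones_induced(set(Joint)), key=lambda b: (b.proximal.value, b.distal.value)
        )
        fa, fb = random_frame(rng), random_frame(rng)
        report = body_similarity(fa, fb, bones)
        n = len(bones)
        # replace the WRIST_R so only the hand bone's similarity changes
        target = Bone(Joint.WRIST_R, Joint.HAND_R)
        s_old = report.bone_sims[target]
        fa2 = SkeletonFrame(fa.timestamp, dict(fa.positions))
        fa2.positions[Joint.HAND_R] = fa.positions[Joint.WRIST_R] + rng.uniform(
            -1, 1, 3
        )
        report2 = body_similarity(fa2, fb, bones)
        s_new = report2.bone_sims[target]
        assert report2.body_similarity - report.body_similarity == pytest.approx(
            (s_new - s_old) / n, abs=1e-9
        )


class TestSequenceSimilarity:
    def test_template_vs_itself_is_100(self, rng):
        seq = random_sequence(rng, n_frames=6)
        assert sequence_similarity(seq, seq, TOPOLOGY) == pytest.approx(
            100.0, abs=1e-5
        )

    def test_double_fps_resampling_invariance(self, rng):
        frames = [random_frame(rng, i / 10.0) for i in range(6)]
        template = SkeletonSequence(frames, 10.0)
        doubled = []
        for i, f in enumerate(frames):
            doubled.append(SkeletonFrame(i / 10.0, dict(f.positions)))
            if i < len(frames) - 1:  # hold each pose for the in-between frame
                doubled.append(SkeletonFrame(i / 10.0 + 0.05, dict(f.positions)))
        window = SkeletonSequence(doubled, 20.0)
        assert abs(window.duration - template.duration) < 1e-9
        assert sequence_similarity(window, template, TOPOLOGY) == pytest.approx(
            100.0, abs=1e-5
        )

    def test_matches_brute_force_resample_then_average(self, rng):
        template = random_sequence(rng, n_frames=7, fps=10.0)
        window = random_sequence(rng, n_frames=9, fps=13.0)
        bones = bones_induced(set(Joint))
        idx = resample_indices(len(window), len(template))
        expected = np.mean(
            [
                brute_force_body_similarity(
                    window.frames[k], template.frames[i], bones
                )
                for i, k in enumerate(idx)
            ]
        )
        assert sequence_similarity(window, template, bones) == pytest.approx(
            expected, abs=1e-9
        )

    def test_speed_mismatch_rejected(self, rng):
        template = random_sequence(rng, n_frames=11, fps=10.0)  # 1.0 s
        short = random_sequence(rng, n_frames=6, fps=10.0)  # 0.5 s
        with pytest.raises(SpeedMismatchError):
            sequence_similarity(short, template, TOPOLOGY)
        # within the ±20% tolerance: accepted
        ok = random_sequence(rng, n_frames=10, fps=10.0)  # 0.9 s
        assert 0.0 <= sequence_similarity(ok, template, TOPOLOGY) <= 100.0

    def test_empty_bone_set_rejected(self, rng):
        seq = random_sequence(rng, 4)
        with pytest.raises(ConfigurationError):
            sequence_similarity(seq, seq, set())
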