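"""Templates, joint-set variants, mirroring, and gated prediction."""

import numpy as np
import pytest

from bodyangles.calibration import LimitTable, default_limits
from bodyangles.errors import ConfigurationError, NoPredictionError
from bodyangles.recognizer import (
    UNKNOWN,
    ActivitySpec,
    ActivityTemplate,
    Extremity,
    JointSetVariant,
    Laterality,
    decide,
    mirror_template,
    predict,
    score_all,
    variant_joints,
)
from bodyangles.skeleton import Joint, SkeletonSequence, mirror_frame
from bodyangles.synthetic import (
    ACTIVITIES,
    NoiseParams,
    generate_sequence,
    make_template,
)

V = JointSetVariant

DRINK_SPEC = ActivitySpec(
    "Drink [D]", "movement", frozenset({Extremity.ARM_R}), Laterality.D
)
LEG_FLEX_SPEC = ActivitySpec(
    "Leg Flexion [I]", "movement", frozenset({Extremity.LEG_L}), Laterality.I
)


class TestVariantJoints:
    def test_vC_is_the_fifteen_joint_set(self):
        joints = variant_joints(DRINK_SPEC, V.vC)
        assert len(joints) == 15
        excluded = {Joint.HAND_L, Joint.HAND_R, Joint.FOOT_L, Joint.FOOT_R, Joint.HEAD}
        assert joints == frozenset(set(Joint) - excluded)
        # vC ignores which extremity the activity uses
        assert variant_joints(LEG_FLEX_SPEC, V.vC) == joints

    def test_vB_right_arm_activity(self):
        assert variant_joints(DRINK_SPEC, V.vB) == frozenset(
            {
                Joint.SHOULDER_R, Joint.ELBOW_R, Joint.WRIST_R,
                Joint.SHOULDER_L, Joint.HIP_L, Joint.HIP_R,
            }
        )

    def test_vT_adds_trunk_to_vB(self):
        vb = variant_joints(LEG_FLEX_SPEC, V.vB)
        vt = variant_joints(LEG_FLEX_SPEC, V.vT)
        assert vt == vb | {Joint.HIP_CENTER, Joint.SPINE, Joint.SHOULDER_CENTER}
        assert Joint.KNEE_L in vb and Joint.ANKLE_L in vb
        assert Joint.FOOT_L not in vb and Joint.HAND_R not in vb


class TestMirrorTemplate:
    def test_involution_and_joint_swap(self, body):
        t = make_template(ACTIVITIES["Drink [D]"], body, V.vB)
        m = mirror_template(t)
        assert m.name == "Drink [I]"
        assert m.laterality is Laterality.I
        assert Joint.WRIST_L in m.relevant_joints
        assert Joint.WRIST_R not in m.relevant_joints
        back = mirror_template(m)
        assert back.name == t.name
        assert back.relevant_joints == t.relevant_joints
        for f0, f1 in zip(t.key_sample.frames, back.key_sample.frames):
            assert f1.allclose(f0)

    def test_symmetric_template_rejected(self, body):
        t = make_template(ACTIVITIES["Stand"], body, V.vC)
        with pytest.raises(ConfigurationError):
            mirror_template(t)

    def test_mirror_equivariance_of_scores(self, body):
        # scoring a mirrored observation against the mirrored template gives
        # the same similarity as the original pair
        t = make_template(ACTIVITIES["Drink [D]"], body, V.vT)
        obs = generate_sequence(
            ACTIVITIES["Grab Object [D]"], body, noise=NoiseParams.zero()
        )
        mirrored_obs = SkeletonSequence(
            [mirror_frame(f) for f in obs.frames], obs.fps
        )
        reports, _ = score_all(obs, [t])
        m_reports, _ = score_all(mirrored_obs, [mirror_template(t)])
        assert m_reports["Drink [I]"].body_similarity == pytest.approx(
            reports["Drink [D]"].body_similarity, abs=1e-9
        )


class TestScoreAll:
    def test_own_key_sample_scores_100(self, body):
        templates = [make_template(ACTIVITIES[a], body, V.vT) for a in ACTIVITIES]
        obs = generate_sequence(
            ACTIVITIES["Drink [D]"], body, noise=NoiseParams.zero()
        )
        reports, unscorable = score_all(obs, templates)
        assert not unscorable
        assert set(reports) == set(ACTIVITIES)
        assert reports["Drink [D]"].body_similarity == pytest.approx(100.0, abs=1e-5)

    def test_empty_registry_scores_nothing(self, body):
        obs = generate_sequence(ACTIVITIES["Stand"], body, noise=NoiseParams.zero())
        reports, unscorable = score_all(obs, [])
        assert reports == {} and unscorable == {}

    def test_incompatible_window_recorded_not_fatal(self, body):
        # observation much shorter than the movement templates' duration
        short = generate_sequence(ACTIVITIES["Stand"], body, noise=NoiseParams.zero())
        short = SkeletonSequence(short.frames[:10], short.fps)  # 0.3 s
        templates = [
            make_template(ACTIVITIES["Walk [D]"], body, V.vT),
            make_template(ACTIVITIES["Stand"], body, V.vT),
        ]
        reports, unscorable = score_all(short, templates)
        assert "Walk [D]" in unscorable  # speed mismatch recorded
        assert "Stand" in reports  # posture still scored on the latest frame


class TestDecide:
    ORDER = ("Stand", "Grab Object [D]", "Drink [D]")

    def test_gated_sink_loses_despite_higher_score(self):
        # a sink activity above the runner-up but below its own limit is
        # excluded, and the best ungated activity wins
        limits = default_limits()
        scores = {"Stand": 84.0, "Grab Object [D]": 83.0}
        label, gated = decide(scores, limits, self.ORDER)
        assert label == "Grab Object [D]"
        assert gated == {"Stand"}

    def test_without_limits_reduces_to_argmax(self):
        scores = {"Stand": 90.0, "Grab Object [D]": 80.0}
        label, gated = decide(scores, None, self.ORDER)
        assert label == "Stand" and gated == frozenset()

    def test_all_below_global_limit_is_unknown(self):
        limits = LimitTable({}, global_limit=50.0)
        label, _ = decide({"Drink [D]": 30.0, "Stand": 42.0}, limits, self.ORDER)
        assert label == UNKNOWN

    def test_all_gated_is_unknown(self):
        limits = LimitTable({"Stand": 90.0}, global_limit=0.0)
        label, gated = decide({"Stand": 85.0}, limits, ("Stand",))
        assert label == UNKNOWN and gated == {"Stand"}

    def test_tie_break_is_registration_order(self):
        scores = {"Drink [D]": 88.0, "Grab Object [D]": 88.0}
        label, _ = decide(scores, None, self.ORDER)
        assert label == "Grab Object [D]"  # registered before Drink in ORDER
        label2, _ = decide(scores, None, ("Drink [D]", "Grab Object [D]"))
        assert label2 == "Drink [D]"

    def test_gating_guarantee_property(self, rng):
        # an activity strictly below its limit is never the prediction
        names = [f"A{i}" for i in range(6)]
        for _ in range(200):
            scores = {n: float(rng.uniform(0, 100)) for n in names}
            limits = LimitTable(
                {n: float(rng.uniform(0, 100)) for n in rng.choice(names, 3, replace=False)},
                global_limit=float(rng.uniform(0, 60)),
            )
            label, gated = decide(scores, limits, names)
            assert label == UNKNOWN or label not in gated
            for n, lim in limits.per_activity.items():
                if scores[n] < lim:
                    assert label != n

    def test_raising_a_limit_never_adds_the_activity(self, rng):
        names = [f"A{i}" for i in range(4)]
        for _ in range(200):
            scores = {n: float(rng.uniform(0, 100)) for n in names}
            lim0 = float(rng.uniform(0, 100))
            target = names[int(rng.integers(4))]
            l1 = LimitTable({target: lim0}, global_limit=0.0)
            l2 = LimitTable({target: min(100.0, lim0 + rng.uniform(0, 30))}, 0.0)
            label1, _ = decide(scores, l1, names)
            label2, _ = decide(scores, l2, names)
            if label1 != target:
                assert label2 != target


class TestPredict:
    def test_template_limits_apply_and_table_overrides(self, body):
        templates = [make_template(ACTIVITIES[a], body, V.vT) for a in ACTIVITIES]
        obs = generate_sequence(
            ACTIVITIES["Leg Flexion [I]"], body, noise=NoiseParams.zero()
        )
        pred = predict(obs, templates, default_limits())
        assert pred.label == "Leg Flexion [I]"
        assert pred.scores["Leg Flexion [I]"] == pytest.approx(100.0, abs=1e-5)

    def test_no_templates_raises(self, body):
        obs = generate_sequence(ACTIVITIES["Stand"], body, noise=NoiseParams.zero())
        with pytest.raises(NoPredictionError):
            predict(obs, [])

    def test_mirrored_world_predicts_mirrored_label(self, body):
        templates = [
            make_template(ACTIVITIES[a], body, V.vT)
            for a in ("Drink [D]", "Grab Object [D]")
        ]
        mirrored_templates = [mirror_template(t) for t in templates]
        obs = generate_sequence(
            ACTIVITIES["Drink [D]"], body, noise=NoiseParams.zero()
        )
        mirrored_obs = SkeletonSequence(
            [mirror_frame(f) for f in obs.frames], obs.fps
        )
        assert predict(obs, templates).label == "Drink [D]"
        assert predict(mirrored_obs, mirrored_templates).label == "Drink [I]"


class TestTemplateSerialization:
    @pytest.mark.filterwarnings("ignore:sink activity")
    @pytest.mark.parametrize("activity", ["Stand", "Drink [D]"])
    def test_json_round_trip(self, body, tmp_path, activity):
        t = make_template(ACTIVITIES[activity], body, V.vT)
        path = tmp_path / "t.json"
        t.to_json(path)
        back = ActivityTemplate.from_json(path)
        assert back.name == t.name
        assert back.kind == t.kind
        assert back.relevant_joints == t.relevant_joints
        assert back.laterality == t.laterality
        assert back.sink == t.sink
        if t.kind == "posture":
            assert back.key_sample.allclose(t.key_sample)
        else:
            assert len(back.key_sample) == len(t.key_sample)
            assert back.key_sample.frames[3].allclose(t.key_sample.frames[3])

    def test_sink_without_limit_warns(self, body):
        t = make_template(ACTIVITIES["Stand"], body, V.vC)
        with pytest.warns(UserWarning, match="minimum limit"):
            ActivityTemplate(
                name=t.name, kind=t.kind, key_sample=t.key_sample,
                relevant_joints=t.relevant_joints, sink=True,
            )
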