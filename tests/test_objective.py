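from dataclasses import replace

import numpy as np
import pytest

from spineplan import (
    ValidationError,
    compute_all,
    load_weight_profiles,
    make_context,
    phi,
    phi_breakdown,
)
from spineplan.objective import ContextError, WeightProfile


@pytest.fixture(scope="module")
def profiles():
    return load_weight_profiles()


@pytest.fixture(scope="module")
def ctx(preop_descriptors):
    return make_context(preop_descriptors, tk_normal=35.0, ll_normal=50.0, F0=10)


def _scaled(ctx, ratio, F):
    """Descriptor set with every normalized ratio equal to ``ratio``."""
    p = ctx.preop
    return replace(
        p,
        theta_PT=p.theta_PT * ratio, theta_MT=p.theta_MT * ratio,
        theta_TLL=p.theta_TLL * ratio, X_AVT=p.X_AVT * ratio,
        theta_TK=ctx.theta_TK_n + (p.theta_TK - ctx.theta_TK_n) * ratio,
        theta_LL=ctx.theta_LL_n + (p.theta_LL - ctx.theta_LL_n) * ratio,
        theta_AVR_PT=p.theta_AVR_PT * ratio, theta_AVR_MT=p.theta_AVR_MT * ratio,
        theta_AVR_TLL=p.theta_AVR_TLL * ratio,
        theta_PMC_PT=p.theta_PMC_PT * ratio, theta_PMC_MT=p.theta_PMC_MT * ratio,
        theta_PMC_TLL=p.theta_PMC_TLL * ratio,
        F=F)


class TestWeightProfiles:
    def test_packaged_table_has_eleven_validated_profiles(self, profiles):
        assert [p.surgeon_id for p in profiles] == [f"S{i}" for i in range(1, 12)]
        for p in profiles:
            p.validate()

    def test_first_profile_global_weights(self, profiles):
        s1 = profiles[0]
        assert (s1.W1, s1.W2, s1.W3, s1.W4) == (30, 30, 20, 20)
        assert (s1.a1, s1.a2, s1.a3, s1.a4) == (10, 50, 0, 40)

    def test_fourth_profile_ignores_mobility(self, profiles):
        assert profiles[3].W4 == 0

    def test_bad_group_sum_rejected(self, profiles):
        bad = replace(profiles[0], a1=0.0)  # a-group now sums to 90
        with pytest.raises(ValidationError, match="group 'a'"):
            bad.validate()

    def test_negative_weight_rejected(self, profiles):
        bad = replace(profiles[0], a1=-10.0, a2=70.0)
        with pytest.raises(ValidationError, match="negative"):
            bad.validate()


class TestContext:
    def test_small_angles_floored_to_five_degrees(self, preop_descriptors):
        raw = replace(preop_descriptors, theta_PT=3.0, theta_AVR_TLL=-2.0)
        ctx = make_context(raw, 35.0, 50.0, F0=10)
        assert ctx.preop.theta_PT == 5.0
        assert ctx.preop.theta_AVR_TLL == -5.0

    def test_small_avt_floored_to_half_cm(self, preop_descriptors):
        raw = replace(preop_descriptors, X_AVT=0.2)
        ctx = make_context(raw, 35.0, 50.0, F0=10)
        assert ctx.preop.X_AVT == 0.5

    def test_normal_sagittal_target_must_differ_from_preop(self, preop_descriptors):
        # preop TK is 22: a normal of 25 is within the 5 degree guard
        with pytest.raises(ContextError):
            make_context(preop_descriptors, tk_normal=25.0, ll_normal=50.0, F0=10)
        make_context(preop_descriptors, tk_normal=35.0, ll_normal=50.0, F0=10)


class TestPhi:
    def test_preoperative_state_scores_exactly_one(self, ctx, profiles):
        d = replace(ctx.preop, F=ctx.F0)
        for p in profiles:
            assert abs(phi(d, ctx, p) - 1.0) < 1e-12, p.surgeon_id

    def test_half_ratio_hand_oracle(self, ctx, profiles):
        # S1 weights W=(30,30,20,20): all geometric ratios 0.5 and F=F0 give
        # 0.3*0.25 + 0.3*0.25 + 0.2*0.25 + 0.2*1 = 0.40
        d = _scaled(ctx, 0.5, ctx.F0)
        assert phi(d, ctx, profiles[0]) == pytest.approx(0.40, abs=1e-12)

    def test_perfect_correction_leaves_only_mobility(self, ctx, profiles):
        d = _scaled(ctx, 0.0, ctx.F0)
        for p in profiles:
            assert phi(d, ctx, p) == pytest.approx(p.W4 / 100.0, abs=1e-12)

    def test_strictly_decreasing_in_unfused_count(self, ctx, profiles):
        vals = [phi(_scaled(ctx, 0.7, F), ctx, profiles[0]) for F in (6, 8, 10)]
        assert vals[0] > vals[1] > vals[2]

    def test_mobility_lower_bound(self, ctx, profiles):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = _scaled(ctx, rng.uniform(0.0, 1.5), int(rng.integers(1, 18)))
            for p in profiles[:3]:
                assert phi(d, ctx, p) >= p.W4 / 100.0 * (ctx.F0 / 17) ** 2 - 1e-12

    def test_ratio_form_invariant_under_joint_scaling(self, preop_descriptors, profiles):
        ctx1 = make_context(preop_descriptors, 35.0, 50.0, F0=10)
        doubled = replace(
            preop_descriptors,
            theta_MT=preop_descriptors.theta_MT * 2.0)
        ctx2 = make_context(doubled, 35.0, 50.0, F0=10)
        d1 = replace(ctx1.preop, theta_MT=ctx1.preop.theta_MT * 0.6, F=10)
        d2 = replace(ctx2.preop, theta_MT=ctx2.preop.theta_MT * 0.6, F=10)
        assert phi(d1, ctx1, profiles[0]) == pytest.approx(
            phi(d2, ctx2, profiles[0]), abs=1e-12)

    def test_zero_unfused_count_rejected(self, ctx, profiles):
        d = _scaled(ctx, 0.5, 0)
        with pytest.raises(ValidationError):
            phi(d, ctx, profiles[0])

    def test_transverse_pairing_switch(self, ctx, profiles):
        # make the AVR and PMC ratios differ so the pairing matters
        d = replace(_scaled(ctx, 0.5, ctx.F0),
                    theta_PMC_PT=ctx.preop.theta_PMC_PT,
                    theta_PMC_MT=ctx.preop.theta_PMC_MT,
                    theta_PMC_TLL=ctx.preop.theta_PMC_TLL)
        table = phi(d, ctx, profiles[0], transverse_pairing="table")
        eq = phi(d, ctx, profiles[0], transverse_pairing="equation")
        assert table != pytest.approx(eq)

    def test_breakdown_sums_to_phi(self, ctx, profiles):
        d = _scaled(ctx, 0.8, 9)
        parts = phi_breakdown(d, ctx, profiles[4])
        assert set(parts) == {"coronal", "sagittal", "transverse", "mobility"}
        assert sum(parts.values()) == pytest.approx(phi(d, ctx, profiles[4]), abs=1e-14)
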