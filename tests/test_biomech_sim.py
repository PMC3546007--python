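import numpy as np
import pytest

from spineplan import (
    InstrumentationConfig,
    StiffnessConfig,
    apply_maneuver,
    build_model,
    compute_all,
    make_implant_plan,
    run_instrumentation,
    shape_rod,
    solve_equilibrium,
)
from spineplan.biomech_sim import _implant_head_rest, tangent_system


@pytest.fixture()
def basic_config():
    return InstrumentationConfig(
        uiv="T4", liv="L2",
        implant_plan=make_implant_plan("T4", "L2", "ends_apex", "screw"),
        rod_thoracic_bend=20.0, rod_lumbar_bend=30.0)


@pytest.fixture()
def model(index_model, basic_config):
    return build_model(index_model, basic_config)


class TestModelStructure:
    def test_chain_has_seventeen_intervertebral_joints(self, model):
        assert model.n_joints == 17  # T1-T2 .. L5-pelvis

    def test_pelvis_keeps_only_sagittal_rotation(self, model):
        act = set(model.layout.active_indices())
        assert model.layout.pelvis in act
        # the pelvis contributes exactly one generalized coordinate
        assert model.layout.pelvis == 6 * 17

    def test_implant_needs_pedicles(self, index_model):
        cfg = InstrumentationConfig(
            uiv="T4", liv="L2",
            implant_plan=make_implant_plan("T4", "L2", "every", "screw"))
        m = build_model(index_model, cfg)
        assert len(m.implants) == 11

    def test_invalid_config_rejected(self, index_model):
        with pytest.raises(Exception):
            InstrumentationConfig(uiv="L2", liv="T4", implant_plan={}).validate()


class TestEquilibrium:
    def test_zero_load_is_stress_free(self, model):
        info = solve_equilibrium(model)
        assert info["iterations"] == 0
        assert info["residual"] < 1e-9
        assert np.abs(model.state.t).max() < 1e-12

    def test_small_load_matches_linearized_solution(self, index_model, basic_config):
        m1 = build_model(index_model, basic_config)
        g, K, act = tangent_system(m1)
        f = np.zeros(m1.layout.n_dof)
        f[m1.layout.vert_t(7)] = [0.0, 1.0, 0.0]  # 1 N lateral at T8
        lin = np.linalg.solve(K, f[act])

        m2 = build_model(index_model, basic_config)
        solve_equilibrium(m2, loads={"T8": (0.0, 1.0, 0.0)})
        # compare the vertebral translations (act is sorted, so position of
        # dof j in the reduced system is its searchsorted index)
        lin_t = np.vstack([
            lin[np.searchsorted(act, 6 * i): np.searchsorted(act, 6 * i) + 3]
            for i in range(17)])
        err = np.linalg.norm(m2.state.t - lin_t) / np.linalg.norm(lin_t)
        assert err < 0.01

    def test_linear_regime_doubling(self, index_model, basic_config):
        u = []
        for scale in (1.0, 2.0):
            m = build_model(index_model, basic_config)
            solve_equilibrium(m, loads={"T8": (0.0, scale, 0.0)})
            u.append(m.state.t[7].copy())
        ratio = np.linalg.norm(u[1]) / np.linalg.norm(u[0])
        assert ratio == pytest.approx(2.0, rel=0.02)


class TestRodShape:
    def test_zero_bends_give_straight_rod(self, index_model, basic_config):
        cfg = InstrumentationConfig(
            uiv="T4", liv="L2",
            implant_plan=make_implant_plan("T4", "L2", "every", "screw"),
            rod_thoracic_bend=0.0, rod_lumbar_bend=0.0)
        rod = shape_rod(cfg, index_model)
        assert rod.arc_length() == pytest.approx(rod.chord_length, rel=1e-6)

    def test_tangent_sweeps_match_bends(self):
        # measure the tangent sweeps of the two arcs on a finely sampled
        # construction curve (chord-angle truncation is negligible there)
        from spineplan.biomech_sim import _two_arc_curve

        f_t = 0.8
        pts = _two_arc_curve(np.deg2rad(30.0), np.deg2rad(45.0), f_t, n=801)
        d = np.diff(pts, axis=0)
        ang = np.unwrap(np.arctan2(d[:, 0], d[:, 1]))
        n_seg = len(ang)
        k = int(round(f_t * n_seg))
        x = np.arange(n_seg) + 0.5  # chord midpoints in sample units

        def sweep(lo, hi):
            # chord angles are linear in arc length within one circular
            # arc, so a linear fit extrapolated to the arc boundaries
            # recovers the tangent sweep without half-segment truncation
            b, _a = np.polyfit(x[lo:hi], ang[lo:hi], 1)
            return abs(np.degrees(b * (hi - lo)))

        assert sweep(0, k) == pytest.approx(30.0, abs=0.1)
        assert sweep(k, n_seg) == pytest.approx(45.0, abs=0.1)

    def test_rod_spans_the_implant_chord(self, index_model, basic_config):
        rod = shape_rod(basic_config, index_model)
        st = StiffnessConfig()
        pA = _implant_head_rest(index_model, "T4", "left", st.head_offset)
        pB = _implant_head_rest(index_model, "L2", "left", st.head_offset)
        w0 = rod.origin + rod.R0 @ rod.points[0]
        w1 = rod.origin + rod.R0 @ rod.points[-1]
        assert np.linalg.norm(w0 - pA) < 5.0
        assert np.linalg.norm(w1 - pB) < 5.0


class TestManeuvers:
    def test_attach_seats_every_implant(self, index_model):
        cfg = InstrumentationConfig(
            uiv="T4", liv="L2",
            implant_plan=make_implant_plan("T4", "L2", "every", "screw"))
        model = build_model(index_model, cfg)
        rod = shape_rod(cfg, index_model)
        apply_maneuver(model, rod, ("attach", {}))
        assert model.seating_gaps().max() < 0.1

    def test_derotation_brings_rod_plane_to_sagittal(self, index_model, basic_config):
        model = build_model(index_model, basic_config)
        rod = shape_rod(basic_config, index_model)
        apply_maneuver(model, rod, ("attach", {}))
        log = apply_maneuver(model, None, ("derotate", {}))
        n = model.rod_plane_normal()
        angle = np.degrees(np.arccos(min(abs(n[1]), 1.0)))
        assert angle <= 0.5
        assert log[-1]["plane_angle_deg"] <= 0.5

    def test_distraction_at_current_distance_is_a_no_op(self, index_model, basic_config):
        model = build_model(index_model, basic_config)
        rod = shape_rod(basic_config, index_model)
        apply_maneuver(model, rod, ("attach", {}))
        before = model.state.h.copy()
        la, lb = model.implants[0]["level"], model.implants[-1]["level"]
        d0 = float(np.linalg.norm(model.state.h[-1] - model.state.h[0]))
        log = apply_maneuver(model, None, ("distract", {"implants": (la, lb),
                                                        "target": d0}))
        assert np.abs(model.state.h - before).max() < 1e-6
        assert log[0]["iterations"] == 0

    def test_compression_reaches_target_separation(self, index_model, basic_config):
        # compression slides the end implants inward along the rod (a rigid
        # rod blocks distraction past its end stops)
        model = build_model(index_model, basic_config)
        rod = shape_rod(basic_config, index_model)
        apply_maneuver(model, rod, ("attach", {}))
        la, lb = model.implants[0]["level"], model.implants[-1]["level"]
        d0 = float(np.linalg.norm(model.state.h[-1] - model.state.h[0]))
        apply_maneuver(model, None, ("compress", {"implants": (la, lb),
                                                  "target": d0 - 5.0}))
        d1 = float(np.linalg.norm(model.state.h[-1] - model.state.h[0]))
        assert d1 == pytest.approx(d0 - 5.0, abs=0.5)


class TestFullSimulation:
    def test_reduces_main_thoracic_cobb(self, index_model, preop_descriptors,
                                        basic_config):
        res = run_instrumentation(index_model, basic_config)
        assert res.converged
        assert res.post_descriptors.theta_MT < preop_descriptors.theta_MT

    def test_unfused_count_comes_from_configuration(self, index_model, basic_config):
        res = run_instrumentation(index_model, basic_config)
        assert res.post_descriptors.F == 17 - basic_config.fused_levels

    def test_every_converged_step_meets_its_tolerance(self, index_model, basic_config):
        res = run_instrumentation(index_model, basic_config)
        steps = [e for e in res.maneuver_log if "residual" in e]
        assert steps
        for e in steps:
            assert e["residual"] <= e["tolerance"]

    def test_bitwise_deterministic(self, index_model, basic_config):
        r1 = run_instrumentation(index_model, basic_config)
        r2 = run_instrumentation(index_model, basic_config)
        for v1, v2 in zip(r1.post_model.vertebrae, r2.post_model.vertebrae):
            assert np.array_equal(v1.points(), v2.points())
        assert r1.post_descriptors.as_dict() == r2.post_descriptors.as_dict()
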