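import numpy as np
import pytest

from spineplan import (
    GeometryError,
    SegmentDef,
    ValidationError,
    apical_translation,
    compute_all,
    coronal_cobb,
    find_inflexion_points,
    generate_spine,
    pmc_orientation,
    sagittal_cobb,
    stokes_avr,
    unfused_count,
)
from spineplan.spine_geometry import SPINE_LEVELS, SpineModel, VertebraGeom

from conftest import make_params
from test_spine_geometry import _vertebra_from_axes


def _arc_spine(sweep_deg: float) -> SpineModel:
    """Body centers on a coronal circular arc of given tangent sweep;
    endplates perpendicular to the exact tangent.  The Cobb angle between
    the end-vertebra perpendiculars equals the sweep (closed form)."""
    n = 17
    total_len = 400.0
    theta = np.deg2rad(sweep_deg)
    radius = total_len / theta
    angles = np.linspace(theta / 2.0, -theta / 2.0, n)
    verts = []
    for i, (lab, a) in enumerate(zip(SPINE_LEVELS, angles)):
        # arc in the y-z plane, apex toward +y (left), z decreasing
        y = radius * (np.cos(a) - np.cos(theta / 2.0))
        z = 500.0 - radius * (np.sin(theta / 2.0) - np.sin(a))
        center = np.array([0.0, y, z])
        zax = np.array([0.0, -np.sin(a), np.cos(a)])
        yax = np.array([0.0, np.cos(a), np.sin(a)])
        xax = np.cross(yax, zax)
        axes = np.column_stack([xax, yax, zax])
        verts.append(_vertebra_from_axes(lab, center, axes))
    pelvis_center = verts[-1].body_center - np.array([0.0, 0.0, 40.0])
    verts.append(_vertebra_from_axes("PELVIS", pelvis_center, np.eye(3)))
    return SpineModel(verts)


class TestInflexionPoints:
    def test_straight_spine_has_none(self, straight_model):
        assert find_inflexion_points(straight_model) == []

    def test_index_fixture_contains_region_boundaries(self, index_model):
        found = find_inflexion_points(index_model)
        assert {"T5", "T11"} <= set(found)

    def test_single_curve_yields_exactly_its_neutral_vertebrae(self):
        m = generate_spine(make_params(mt=30.0))
        assert find_inflexion_points(m) == ["T5", "T11"]


class TestCoronalCobb:
    @pytest.mark.parametrize("sweep", [10.0, 30.0, 50.0, 70.0, 90.0])
    def test_analytic_arc_equals_tangent_sweep(self, sweep):
        # tangent angles on the arc are linear in arc length, so the
        # T2..L4 segment subtends exactly 14/16 of the full sweep
        m = _arc_spine(sweep)
        seg = SegmentDef("MT", "T2", "L4", apex="T9")
        angle, side = coronal_cobb(m, seg)
        assert angle == pytest.approx(sweep * 14.0 / 16.0, abs=0.1)
        assert side == "left"

    def test_straight_spine_measures_zero(self, straight_model):
        seg = SegmentDef("MT", "T5", "T11", apex="T8")
        angle, side = coronal_cobb(straight_model, seg)
        assert angle == pytest.approx(0.0, abs=1e-9)
        assert side == "none"

    def test_index_main_thoracic_is_right(self, index_model):
        angle, side = coronal_cobb(index_model, SegmentDef("MT", "T5", "T11", apex="T8"))
        assert angle == pytest.approx(56.0, abs=0.5)
        assert side == "right"


class TestSagittalCobb:
    def test_horizontal_endplates_measure_zero(self, straight_model):
        assert sagittal_cobb(straight_model, SegmentDef("TK", "T4", "T12")) == \
            pytest.approx(0.0, abs=1e-9)
        assert sagittal_cobb(straight_model, SegmentDef("LL", "T12", "L5")) == \
            pytest.approx(0.0, abs=1e-9)

    def test_kyphotic_and_lordotic_bows_measure_positive(self):
        m = generate_spine(make_params(kyph=20.0, lord=30.0))
        assert sagittal_cobb(m, SegmentDef("TK", "T4", "T12")) > 5.0
        assert sagittal_cobb(m, SegmentDef("LL", "T12", "L5")) > 5.0


class TestApicalTranslation:
    def test_straight_spine_is_zero(self, straight_model):
        assert apical_translation(straight_model, "T8") == pytest.approx(0.0)

    def test_invariant_under_rigid_lateral_shift(self, index_model):
        shifted = SpineModel([
            VertebraGeom.from_points(v.label, v.points() + np.array([0, 25.0, 0]))
            for v in index_model.vertebrae])
        assert apical_translation(shifted, "T8") == pytest.approx(
            apical_translation(index_model, "T8"), abs=1e-9)

    def test_constructed_offset_in_cm(self, straight_model):
        moved = straight_model.copy()
        idx = list(SPINE_LEVELS).index("T8")
        pts = moved.vertebrae[idx].points() + np.array([0.0, 20.0, 0.0])
        moved.vertebrae[idx] = VertebraGeom.from_points("T8", pts)
        assert apical_translation(moved, "T8") == pytest.approx(2.0, abs=0.01)


class TestStokesRotation:
    def test_unrotated_vertebra_is_zero(self, straight_model):
        assert stokes_avr(straight_model, "T8") == pytest.approx(0.0, abs=1e-9)

    def test_constructed_rotation_recovered(self):
        m = generate_spine(make_params(mt=25.0, rot_mt=20.0))
        assert stokes_avr(m, "T8") == pytest.approx(20.0, abs=0.5)

    def test_mirror_reflection_flips_sign(self):
        m = generate_spine(make_params(mt=25.0, rot_mt=12.0))
        mirrored = SpineModel([
            VertebraGeom.from_points(v.label, v.points() * np.array([1.0, -1.0, 1.0]))
            for v in m.vertebrae])
        # reflection swaps the pedicle labels too
        for v in mirrored.vertebrae:
            v.left_pedicle, v.right_pedicle = (v.right_pedicle.copy(),
                                               v.left_pedicle.copy())
        assert stokes_avr(mirrored, "T8") == pytest.approx(
            -stokes_avr(m, "T8"), abs=1e-9)


class TestPlaneOfMaxCurvature:
    def test_pure_coronal_deformity_is_90(self):
        m = generate_spine(make_params(mt=30.0))
        seg = SegmentDef("MT", "T5", "T11", apex="T8")
        assert pmc_orientation(m, seg) == pytest.approx(90.0, abs=1e-6)

    def test_pure_sagittal_bow_is_0(self):
        m = generate_spine(make_params(kyph=25.0))
        seg = SegmentDef("MT", "T5", "T11", apex="T8")
        assert pmc_orientation(m, seg) == pytest.approx(0.0, abs=1e-6)

    def test_equal_coronal_and_sagittal_deflection_is_45(self):
        verts = []
        z0 = 500.0
        for i, lab in enumerate(SPINE_LEVELS):
            t = i / 16.0
            off = 20.0 * np.sin(np.pi * t)
            center = np.array([-off, -off, z0 - 24.0 * i])
            verts.append(_vertebra_from_axes(lab, center, np.eye(3)))
        verts.append(_vertebra_from_axes(
            "PELVIS", verts[-1].body_center - np.array([0, 0, 40.0]), np.eye(3)))
        m = SpineModel(verts)
        seg = SegmentDef("MT", "T1", "L5", apex="T9")
        assert pmc_orientation(m, seg) == pytest.approx(45.0, abs=0.5)

    def test_collinear_segment_raises(self, straight_model):
        with pytest.raises(GeometryError):
            pmc_orientation(straight_model, SegmentDef("MT", "T5", "T11", apex="T8"))


class TestUnfusedCount:
    def test_eleven_fused_vertebrae_leave_six(self):
        # T4..L2 inclusive instruments 11 vertebrae
        assert unfused_count(("T4", "L2")) == 6

    def test_no_instrumentation(self):
        assert unfused_count(None) == 17

    def test_full_fusion(self):
        assert unfused_count(("T1", "L5")) == 0

    def test_inverted_span_rejected(self):
        with pytest.raises(ValidationError):
            unfused_count(("L2", "T4"))


class TestComputeAll:
    def test_straight_spine_all_zero(self, straight_model):
        d = compute_all(straight_model)
        for name in ("theta_PT", "theta_MT", "theta_TLL", "X_AVT",
                     "theta_TK", "theta_LL", "theta_AVR_PT", "theta_AVR_MT",
                     "theta_AVR_TLL", "theta_PMC_PT", "theta_PMC_MT",
                     "theta_PMC_TLL"):
            assert getattr(d, name) == pytest.approx(0.0, abs=1e-9), name
        assert d.F == 17

    def test_bitwise_deterministic(self, index_model):
        d1 = compute_all(index_model).as_dict()
        d2 = compute_all(index_model).as_dict()
        assert d1 == d2
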