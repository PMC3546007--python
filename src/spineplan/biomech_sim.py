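"""Simplified quasi-static flexible-multibody model of the instrumented
spine and the three corrective manoeuvres (rod attachment, rod derotation,
compression/distraction).

Model structure
---------------
Each vertebra (T1..L5) is a rigid body with 6 degrees of freedom; the pelvis
is fixed except for sagittal-plane rotation; T1 translates freely and
rotates freely in the frontal plane, with weak springs restraining its
remaining rotations.  Adjacent bodies are coupled by 6-component
generalized springs (diagonal translational/rotational stiffness) located
at the midpoint between body centers, stress-free in the preoperative
reference configuration.  Implants are point bodies offset posteriorly from
their pedicle entry, connected to the vertebra by a piecewise-linear
stiffening spring (soft toe region, stiff engagement) — the generalized
nonlinear implant-vertebra link.  The rod is a rigid planar two-arc body.

Manoeuvres are load-driven: rod attachment ramps up point-to-curve seating
springs that become cylindrical joints (free sliding along and rotation
about the rod axis); derotation applies a stiff rotational drive that turns
the rod plane from its initial coronal orientation to the sagittal plane;
compression/distraction ramps a force between two implants until their
separation reaches a target.  Equilibrium at every increment is found by a
damped Newton iteration (Gauss-Newton Hessian, energy line search) with
automatic increment halving, so every converged state satisfies the
generalized force balance to tolerance.

Units: N, mm, rad (degrees at the public interfaces).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._so3 import exp_so3, left_jacobian_inv, log_so3, right_jacobian_inv, skew
from .descriptors import DescriptorSet, SegmentDef, compute_all, default_segments
from .spine_geometry import (
    SPINE_LEVELS,
    SpineModel,
    SpinePlanError,
    ValidationError,
    VertebraGeom,
    level_index,
)

__all__ = [
    "StiffnessConfig",
    "InstrumentationConfig",
    "RodGeometry",
    "FlexSpineModel",
    "SimResult",
    "SimulationError",
    "ManeuverError",
    "make_implant_plan",
    "build_model",
    "shape_rod",
    "solve_equilibrium",
    "apply_maneuver",
    "run_instrumentation",
]

_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([1.0, 0.0, 0.0])
_EYE3 = np.eye(3)


class SimulationError(SpinePlanError):
    """The equilibrium iteration failed to converge."""


class ManeuverError(SpinePlanError):
    """A corrective manoeuvre could not be completed."""


@dataclass
class StiffnessConfig:
    """Mechanical parameters of the simplified spine model.

    Intervertebral stiffnesses are diagonal 6-DOF values in the global
    frame of the intraoperative pose (shear/axial translations, N/mm;
    lateral bending / flexion-extension / axial torsion, N*mm/rad), drawn
    from published functional-spinal-unit ranges; implant-vertebra links
    use a soft toe region k1 up to delta0 and a stiff engagement k2 beyond.
    All values are configurable; none are calibrated to a specific patient.
    """

    iv_translation: tuple[float, float, float] = (100.0, 100.0, 300.0)
    iv_rotation: tuple[float, float, float] = (1.5e5, 1.5e5, 3.0e5)
    t1_soft_rotation: float = 1.0e4      # N*mm/rad on T1 sagittal/axial rotation
    screw_k1: float = 200.0              # N/mm, toe region
    screw_k2: float = 2000.0             # N/mm, engaged
    screw_delta0: float = 0.3            # mm
    screw_dir_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    hook_k1: float = 100.0
    hook_k2: float = 1000.0
    hook_delta0: float = 0.5
    hook_dir_weights: tuple[float, float, float] = (1.0, 1.0, 0.2)
    head_offset: float = 10.0            # mm posterior of the pedicle entry
    k_attach: float = 2.0e4              # N/mm, implant-rod seating/joint
    rod_hold_translation: float = 0.5    # N/mm, weak grip regularizing free sliding
    rod_hold_rotation: float = 1.0e4     # N*mm/rad, weak grip on rod roll
    k_drive: float = 1.0e9               # N*mm, derotation drive
    k_compdist: float = 2000.0           # N/mm, compression/distraction drive
    attach_ramp: tuple[float, ...] = (0.002, 0.02, 0.2, 1.0)
    derot_step_deg: float = 15.0
    rtol: float = 1e-6                   # residual tolerance x characteristic load
    max_newton: int = 60
    max_halvings: int = 5


@dataclass
class InstrumentationConfig:
    """One candidate instrumentation strategy.

    ``implant_plan`` maps instrumented levels to implant type ('screw' or
    'hook'); UIV and LIV must carry implants.  Rod bends are the tangent
    sweeps (deg) of the thoracic and lumbar arcs of the planar rod."""

    uiv: str
    liv: str
    implant_plan: dict[str, str]
    rod_thoracic_bend: float = 20.0
    rod_lumbar_bend: float = 30.0
    rod_side: str = "auto"               # 'left' | 'right' | 'auto' (concave of MT)
    maneuver_sequence: tuple = (("attach", {}), ("derotate", {}))

    def validate(self) -> None:
        iu, il = level_index(self.uiv), level_index(self.liv)
        if il >= len(SPINE_LEVELS):
            raise ValidationError("LIV must lie within T1..L5")
        if iu >= il:
            raise ValidationError(f"UIV {self.uiv} must be above LIV {self.liv}")
        for lvl, typ in self.implant_plan.items():
            if not iu <= level_index(lvl) <= il:
                raise ValidationError(f"implant at {lvl} outside [{self.uiv}, {self.liv}]")
            if typ not in ("screw", "hook"):
                raise ValidationError(f"unknown implant type {typ!r} at {lvl}")
        for end in (self.uiv, self.liv):
            if end not in self.implant_plan:
                raise ValidationError(f"end vertebra {end} carries no implant")
        for bend in (self.rod_thoracic_bend, self.rod_lumbar_bend):
            if not 0.0 <= bend <= 80.0:
                raise ValidationError(f"rod bend {bend} outside [0, 80] deg")

    @property
    def fused_levels(self) -> int:
        return level_index(self.liv) - level_index(self.uiv) + 1

    @property
    def n_implants(self) -> int:
        return len(self.implant_plan)


def make_implant_plan(uiv: str, liv: str, density: str = "every",
                      implant_type: str = "screw",
                      apexes: Sequence[str] = ("T3", "T8", "L2")) -> dict[str, str]:
    """Implant layout over the fused span.

    density: 'every' level, 'alternate' (every other level, both ends kept),
    or 'ends_apex' (UIV, LIV and contained curve apexes).  implant_type:
    'screw' everywhere or 'hybrid' (hooks at the two uppermost implant
    levels, screws below)."""
    iu, il = level_index(uiv), level_index(liv)
    span = list(SPINE_LEVELS[iu : il + 1])
    if density == "every":
        levels = span
    elif density == "alternate":
        levels = span[::2]
        if span[-1] not in levels:
            levels.append(span[-1])
    elif density == "ends_apex":
        levels = [span[0]] + [a for a in apexes if a in span[1:-1]] + [span[-1]]
    else:
        raise ValidationError(f"unknown implant density {density!r}")
    if implant_type == "screw":
        types = ["screw"] * len(levels)
    elif implant_type == "hybrid":
        types = ["hook", "hook"] + ["screw"] * (len(levels) - 2)
        types = types[: len(levels)]
    else:
        raise ValidationError(f"unknown implant pattern {implant_type!r}")
    return dict(zip(levels, types))


# ---------------------------------------------------------------------------
# Rod geometry
# ---------------------------------------------------------------------------

@dataclass
class RodGeometry:
    """Planar two-arc rod: sampled centerline in the rod's own frame
    (x = in-plane bulge, y = plane normal, z = chord), plus its initial
    world placement (plane coronal, bulge toward the main-curve convexity).
    """

    points: np.ndarray          # (n, 3) rod-frame samples, mm
    origin: np.ndarray          # world position of the first sample
    R0: np.ndarray              # rod frame -> world (columns: bulge, normal, chord)
    thoracic_sweep: float       # deg
    lumbar_sweep: float         # deg
    thoracic_fraction: float

    @property
    def chord_length(self) -> float:
        return float(self.points[-1, 2])

    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _two_arc_curve(theta_t: float, theta_l: float, f_t: float,
                   n: int = 121) -> np.ndarray:
    """Unit-chord planar curve: thoracic arc (sweep theta_t, bulge +x) then
    lumbar arc (sweep theta_l, opposite curvature), tangent-continuous.
    Returns (n, 2) points (bulge, chord) with endpoints (0,0) and (0,1)."""
    m = 800
    sigma = np.linspace(0.0, 1.0, m + 1)
    ang = np.empty(m + 1)
    for i, sg in enumerate(sigma):
        if f_t > 0 and sg <= f_t:
            ang[i] = 0.5 * theta_t - theta_t * sg / f_t
        elif f_t < 1.0:
            ang[i] = -0.5 * theta_t + theta_l * (sg - f_t) / (1.0 - f_t)
        else:
            ang[i] = -0.5 * theta_t
    # tangent in (bulge, chord) coordinates; integrate
    d = np.column_stack([np.sin(ang), np.cos(ang)]) / m
    pts = np.vstack([[0.0, 0.0], np.cumsum(d[:-1], axis=0)])
    # rotate in-plane so the chord aligns with +chord axis, scale to unit chord
    chord = pts[-1]
    clen = np.linalg.norm(chord)
    c, s = chord[1] / clen, chord[0] / clen
    rot = np.array([[c, -s], [s, c]])
    pts = pts @ rot.T / clen
    idx = np.linspace(0, m, n).astype(int)
    return pts[idx]


def shape_rod(config: InstrumentationConfig, spine: SpineModel,
              stiffness: StiffnessConfig | None = None,
              mt_apex: str = "T8") -> RodGeometry:
    """Contour and place the rod for a strategy.

    The planar rod consists of two tangent circular-arc segments whose
    tangent sweeps equal the configured thoracic and lumbar bends, with the
    arc-length split at T12 (proportionally to the instrumented span).  It
    is scaled to span the chord between the UIV and LIV implant heads and
    initially oriented with its plane coronal and the thoracic bulge toward
    the main-curve convexity."""
    config.validate()
    st = stiffness or StiffnessConfig()
    iu, il = level_index(config.uiv), level_index(config.liv)
    i12 = level_index("T12")
    n_span = il - iu
    f_t = 1.0 if n_span == 0 else float(np.clip((min(i12, il) - iu) / n_span, 0.0, 1.0))
    pts2 = _two_arc_curve(np.deg2rad(config.rod_thoracic_bend),
                          np.deg2rad(config.rod_lumbar_bend), f_t)

    side = _rod_side(config, spine, mt_apex)
    pA = _implant_head_rest(spine, config.uiv, side, st.head_offset)
    pB = _implant_head_rest(spine, config.liv, side, st.head_offset)
    chord = pB - pA
    clen = float(np.linalg.norm(chord))
    c_hat = chord / clen

    # bulge toward the main-curve convexity, in the coronal plane
    apex_y = spine[mt_apex].body_center[1] if mt_apex in config_span(config) else \
        spine[SPINE_LEVELS[(iu + il) // 2]].body_center[1]
    dev = apex_y - 0.5 * (pA[1] + pB[1])
    sign = 1.0 if dev >= 0 else -1.0
    v_raw = _Y - (_Y @ c_hat) * c_hat
    v_hat = sign * v_raw / np.linalg.norm(v_raw)
    n_hat = np.cross(c_hat, v_hat)
    R0 = np.column_stack([v_hat, n_hat, c_hat])

    points = np.column_stack([pts2[:, 0] * clen, np.zeros(len(pts2)), pts2[:, 1] * clen])
    return RodGeometry(points=points, origin=pA.copy(), R0=R0,
                       thoracic_sweep=config.rod_thoracic_bend,
                       lumbar_sweep=config.rod_lumbar_bend,
                       thoracic_fraction=f_t)


def config_span(config: InstrumentationConfig) -> list[str]:
    return list(SPINE_LEVELS[level_index(config.uiv): level_index(config.liv) + 1])


def _rod_side(config: InstrumentationConfig, spine: SpineModel, mt_apex: str) -> str:
    if config.rod_side in ("left", "right"):
        return config.rod_side
    # concave side of the main curve: opposite the apex deviation
    dev = spine[mt_apex].body_center[1] - 0.5 * (
        spine[config.uiv].body_center[1] + spine[config.liv].body_center[1])
    return "left" if dev < 0 else "right"


def _implant_head_rest(spine: SpineModel, level: str, side: str,
                       head_offset: float) -> np.ndarray:
    v = spine[level]
    ped = v.left_pedicle if side == "left" else v.right_pedicle
    return ped - head_offset * v.frame.x


# ---------------------------------------------------------------------------
# Elements and state
# ---------------------------------------------------------------------------

class _State:
    """Generalized positions of all bodies."""

    def __init__(self, n_verts: int, n_imp: int):
        self.t = np.zeros((n_verts, 3))
        self.R = np.tile(np.eye(3), (n_verts, 1, 1))
        self.alpha = 0.0
        self.rod_t = np.zeros(3)
        self.rod_R = np.eye(3)   # applied on the left of the placement R0
        self.h = np.zeros((n_imp, 3))

    def copy(self) -> "_State":
        s = _State(len(self.t), len(self.h))
        s.t = self.t.copy(); s.R = self.R.copy(); s.alpha = self.alpha
        s.rod_t = self.rod_t.copy(); s.rod_R = self.rod_R.copy(); s.h = self.h.copy()
        return s

    def apply(self, delta: np.ndarray, layout: "_Layout", scale: float = 1.0) -> None:
        d = delta * scale
        for i in range(len(self.t)):
            self.t[i] += d[layout.vert_t(i)]
            w = d[layout.vert_w(i)]
            if np.any(w):
                self.R[i] = exp_so3(w) @ self.R[i]
        self.alpha += d[layout.pelvis]
        if layout.rod_active:
            self.rod_t += d[layout.rod_t]
            w = d[layout.rod_w]
            if np.any(w):
                self.rod_R = exp_so3(w) @ self.rod_R
        for k in range(len(self.h)):
            self.h[k] += d[layout.imp(k)]


class _Layout:
    def __init__(self, n_verts: int, n_imp: int):
        self.n_verts = n_verts
        self.n_imp = n_imp
        self.pelvis = 6 * n_verts
        self._rod0 = self.pelvis + 1
        self._imp0 = self._rod0 + 6
        self.n_dof = self._imp0 + 3 * n_imp
        self.rod_active = False

    def vert_t(self, i: int) -> slice:
        return slice(6 * i, 6 * i + 3)

    def vert_w(self, i: int) -> slice:
        return slice(6 * i + 3, 6 * i + 6)

    @property
    def rod_t(self) -> slice:
        return slice(self._rod0, self._rod0 + 3)

    @property
    def rod_w(self) -> slice:
        return slice(self._rod0 + 3, self._rod0 + 6)

    def imp(self, k: int) -> slice:
        return slice(self._imp0 + 3 * k, self._imp0 + 3 * k + 3)

    def active_indices(self) -> np.ndarray:
        idx = list(range(self.pelvis + 1))
        if self.rod_active:
            idx += list(range(self._rod0, self._rod0 + 6))
        idx += list(range(self._imp0, self.n_dof))
        return np.array(idx, dtype=int)


@dataclass
class SimResult:
    """Outcome of one instrumentation simulation."""

    post_model: SpineModel
    post_descriptors: DescriptorSet | None
    converged: bool
    residual: float
    maneuver_log: list


class FlexSpineModel:
    """Assembled multibody model: reference geometry, bodies, joints,
    implant links, and (once attached) the rod and manoeuvre drives."""

    def __init__(self, spine: SpineModel, config: InstrumentationConfig,
                 stiffness: StiffnessConfig):
        self.spine0 = spine
        self.config = config
        self.stiffness = stiffness
        self.labels = list(SPINE_LEVELS)
        self.c0 = spine.body_centers(self.labels)          # (17, 3)
        self.pelvis_c0 = spine["PELVIS"].body_center.copy()

        # intervertebral joints: one per adjacent pair incl. L5-pelvis
        self.joint_m0 = []
        for i in range(len(self.labels)):
            lower_c = self.c0[i + 1] if i + 1 < len(self.labels) else self.pelvis_c0
            self.joint_m0.append(0.5 * (self.c0[i] + lower_c))
        self.n_joints = len(self.joint_m0)

        # implants
        side = _rod_side(config, spine, "T8")
        self.rod_side = side
        self.implants = []
        for lvl in sorted(config.implant_plan, key=level_index):
            typ = config.implant_plan[lvl]
            vi = level_index(lvl)
            v = spine[lvl]
            ped = v.left_pedicle if side == "left" else v.right_pedicle
            if not np.all(np.isfinite(ped)):
                raise ValidationError(f"implant level {lvl} lacks pedicle landmarks")
            h0 = _implant_head_rest(spine, lvl, side, stiffness.head_offset)
            if typ == "screw":
                mech = (stiffness.screw_k1, stiffness.screw_k2,
                        stiffness.screw_delta0, np.array(stiffness.screw_dir_weights))
            else:
                mech = (stiffness.hook_k1, stiffness.hook_k2,
                        stiffness.hook_delta0, np.array(stiffness.hook_dir_weights))
            w = np.sqrt(mech[3])
            self.implants.append({"level": lvl, "type": typ, "vert": vi,
                                  "h0": h0, "k1": mech[0], "k2": mech[1],
                                  "delta0": mech[2], "dirw": mech[3],
                                  "Rv0": v.frame.axes.copy(), "w": w,
                                  "eref": w * (v.frame.axes.T @ (h0 - v.body_center))})

        self.layout = _Layout(len(self.labels), len(self.implants))
        self.state = _State(len(self.labels), len(self.implants))
        for k, imp in enumerate(self.implants):
            self.state.h[k] = imp["h0"]

        self.rod: RodGeometry | None = None
        self._rod_segments = None
        self.attach_scale = 0.0
        self.drive_target: np.ndarray | None = None
        self.compdist: tuple[int, int, float] | None = None
        self.external_loads: list[tuple[int, np.ndarray]] = []

        # gradient scaling: rotational entries are N*mm, translational N
        self._gscale = np.ones(self.layout.n_dof)
        for i in range(len(self.labels)):
            self._gscale[self.layout.vert_w(i)] = 1.0 / 100.0
        self._gscale[self.layout.pelvis] = 1.0 / 100.0
        self._gscale[self.layout.rod_w] = 1.0 / 100.0

        # static per-element dof index arrays (hot path)
        lay = self.layout
        self._idx_joint = []
        for i in range(self.n_joints):
            if i + 1 < len(self.labels):
                self._idx_joint.append(np.r_[np.arange(6 * i, 6 * i + 6),
                                             np.arange(6 * (i + 1), 6 * (i + 1) + 6)])
            else:
                self._idx_joint.append(np.r_[np.arange(6 * i, 6 * i + 6), [lay.pelvis]])
        self._idx_link = [np.r_[np.arange(6 * imp["vert"], 6 * imp["vert"] + 6),
                                np.arange(lay.imp(k).start, lay.imp(k).stop)]
                          for k, imp in enumerate(self.implants)]
        self._idx_attach = [np.r_[np.arange(lay.rod_t.start, lay.rod_t.stop),
                                  np.arange(lay.rod_w.start, lay.rod_w.stop),
                                  np.arange(lay.imp(k).start, lay.imp(k).stop)]
                            for k in range(len(self.implants))]
        self._idx_rod_t = np.arange(lay.rod_t.start, lay.rod_t.stop)
        self._idx_rod_w = np.arange(lay.rod_w.start, lay.rod_w.stop)
        self._idx_t1rot = np.arange(3, 6)
        self._ix_cache: dict[int, tuple] = {}
        for arr in (self._idx_joint + self._idx_link + self._idx_attach
                    + [self._idx_rod_t, self._idx_rod_w, self._idx_t1rot]):
            self._ix_cache[id(arr)] = np.ix_(arr, arr)

    # -- kinematics ---------------------------------------------------------

    def rod_world(self, state: _State) -> tuple[np.ndarray, np.ndarray]:
        Rw = state.rod_R @ self.rod.R0
        ow = self.rod.origin + state.rod_t
        return ow, Rw

    def rod_plane_normal(self, state: _State | None = None) -> np.ndarray:
        state = state or self.state
        _, Rw = self.rod_world(state)
        return Rw[:, 1]

    def set_rod(self, rod: RodGeometry) -> None:
        self.rod = rod
        self.layout.rod_active = True
        pts = rod.points
        d = np.diff(pts, axis=0)
        self._rod_segments = (pts[:-1], d)
        # node-averaged unit tangents give a continuously varying joint
        # axis along the polyline (C0 tangent field)
        u = d / np.linalg.norm(d, axis=1, keepdims=True)
        node_u = np.vstack([u[:1], 0.5 * (u[:-1] + u[1:]), u[-1:]])
        self._rod_node_tangents = node_u / np.linalg.norm(node_u, axis=1, keepdims=True)

    def _closest_on_rod(self, h_rodframe: np.ndarray):
        """(foot point, unit tangent, clamped?) on the rod polyline."""
        a, d = self._rod_segments
        L2 = np.einsum("ij,ij->i", d, d)
        t = np.clip(np.einsum("ij,ij->i", h_rodframe - a, d) / L2, 0.0, 1.0)
        foot = a + t[:, None] * d
        dist2 = np.einsum("ij,ij->i", h_rodframe - foot, h_rodframe - foot)
        j = int(np.argmin(dist2))
        tj = float(t[j])
        u = d[j] / np.sqrt(L2[j])
        # interior: the foot lies strictly inside a segment, so the residual
        # is perpendicular to u and the joint is free along u; at a node or
        # rod end the full 3D pull applies (sliding stop / corner wedge)
        interior = 0.0 < tj < 1.0
        return foot[j], u, interior

    # -- element contributions ---------------------------------------------

    def _terms(self, state: _State, need_jac: bool = True):
        """Yield (dof_idx, J, K, e, curv) per elastic element.

        K is the diagonal stiffness (m,); ``curv`` lists the curvature
        (geometric-stiffness) data completing the Newton Hessian beyond the
        Gauss-Newton part: 'rot3' adds the second derivative of
        f . A exp(w) u on a rotation block, 'alpha' its projection on the
        pelvis sagittal axis, 'cross' the rotation-translation coupling,
        'rank1' a directional stiffness correction, and 'dist' the
        curvature of the implant-separation constraint.  With
        ``need_jac=False`` only (idx, None, K, e, None) is produced — the
        cheap path used by the energy evaluation."""
        lay = self.layout
        st = self.stiffness
        Kt = np.array(st.iv_translation)
        Kr = np.array(st.iv_rotation)
        Rp = exp_so3(state.alpha * _Y)
        n_vert = len(self.labels)
        for i in range(self.n_joints):
            m0 = self.joint_m0[i]
            ua = state.R[i] @ (m0 - self.c0[i])
            pa = self.c0[i] + state.t[i] + ua
            last = i + 1 >= n_vert
            if not last:
                ub = state.R[i + 1] @ (m0 - self.c0[i + 1])
                pb = self.c0[i + 1] + state.t[i + 1] + ub
                psi = log_so3(state.R[i] @ state.R[i + 1].T)
            else:  # L5 - pelvis
                ub = Rp @ (m0 - self.pelvis_c0)
                pb = self.pelvis_c0 + ub
                psi = log_so3(state.R[i] @ Rp.T)
            idx = self._idx_joint[i]
            if not need_jac:
                yield idx, None, Kt, pa - pb, None
                yield idx, None, Kr, psi, None
                continue
            if not last:
                Jt = np.zeros((3, 12))
                Jt[:, 0:3] = _EYE3
                Jt[:, 3:6] = -skew(ua)
                Jt[:, 6:9] = -_EYE3
                Jt[:, 9:12] = skew(ub)
                Jr = np.zeros((3, 12))
                Jr[:, 3:6] = left_jacobian_inv(psi)
                Jr[:, 9:12] = -right_jacobian_inv(psi)
                curv = [("rot3", 6 * i + 3, ua, _EYE3),
                        ("rot3", 6 * (i + 1) + 3, ub, -_EYE3)]
            else:
                Jt = np.zeros((3, 7))
                Jt[:, 0:3] = _EYE3
                Jt[:, 3:6] = -skew(ua)
                Jt[:, 6] = -np.cross(_Y, ub)
                Jr = np.zeros((3, 7))
                Jr[:, 3:6] = left_jacobian_inv(psi)
                Jr[:, 6] = -right_jacobian_inv(psi) @ _Y
                curv = [("rot3", 6 * i + 3, ua, _EYE3),
                        ("alpha", lay.pelvis, ub, -_EYE3)]
            yield idx, Jt, Kt, pa - pb, curv
            yield idx, Jr, Kr, psi, []

        # T1 soft rotational restraint (sagittal + axial; frontal free)
        psi1 = log_so3(state.R[0])
        K1 = np.array([st.t1_soft_rotation, st.t1_soft_rotation])
        if need_jac:
            yield (self._idx_t1rot, left_jacobian_inv(psi1)[[1, 2], :],
                   K1, psi1[[1, 2]], [])
        else:
            yield self._idx_t1rot, None, K1, psi1[[1, 2]], None

        # implant-vertebra nonlinear links (soft toe, stiff engagement)
        for k, imp in enumerate(self.implants):
            vi = imp["vert"]
            Rv = state.R[vi] @ imp["Rv0"]
            w = imp["w"]
            rel = state.h[k] - self.c0[vi] - state.t[vi]
            e = w * (Rv.T @ rel) - imp["eref"]
            m = float(np.sqrt(e @ e))
            if m <= imp["delta0"]:
                ksec = imp["k1"]
                ktan = imp["k1"]
            else:
                ksec = (imp["k1"] * imp["delta0"]
                        + imp["k2"] * (m - imp["delta0"])) / m
                ktan = imp["k2"]
            Kl = np.array([ksec, ksec, ksec])
            idx = self._idx_link[k]
            if not need_jac:
                yield idx, None, Kl, e, None
                continue
            J = np.zeros((3, 9))
            RvT = Rv.T
            J[:, 0:3] = -(w[:, None] * RvT)
            J[:, 3:6] = w[:, None] * (RvT @ skew(rel))
            J[:, 6:9] = w[:, None] * RvT
            # e contains w Rv^T exp(-w) rel, so A^T f = Rv (w * f); the
            # piecewise stiffening adds a rank-1 tangent term along e
            phi = Rv @ (w * (ksec * e))
            curv = [("rot3", 6 * vi + 3, rel, Rv * w[None, :]),
                    ("cross", 6 * vi + 3, lay.imp(k).start, +1.0, phi),
                    ("cross", 6 * vi + 3, 6 * vi, -1.0, phi)]
            if m > 1e-12 and ktan != ksec:
                curv.append(("rank1", ktan - ksec, e / m))
            yield idx, J, Kl, e, curv

        # implant-rod attachment (cylindrical joints once seated)
        if self.rod is not None and self.attach_scale > 0.0:
            ow, Rw = self.rod_world(state)
            k_att = st.k_attach * self.attach_scale
            Ka = np.array([k_att, k_att, k_att])
            RwT = Rw.T
            for k in range(len(self.implants)):
                hk = state.h[k]
                hprime = RwT @ (hk - ow)
                foot, u, interior = self._closest_on_rod(hprime)
                # E = k/2 dist^2(head, rod curve); with the foot frozen the
                # gradient k (h' - foot) is exact (Danskin), and the free
                # sliding of the cylindrical joint appears as a negative
                # rank-1 tangential term in the Hessian
                e = hprime - foot
                idx = self._idx_attach[k]
                if not need_jac:
                    yield idx, None, Ka, e, None
                    continue
                J = np.zeros((3, 9))
                J[:, 0:3] = -RwT
                J[:, 3:6] = RwT @ skew(hk - ow)
                J[:, 6:9] = RwT
                phi = Rw @ (k_att * e)
                curv = [("rot3", lay.rod_w.start, hk - ow, Rw),
                        ("cross", lay.rod_w.start, lay.imp(k).start, +1.0, phi),
                        ("cross", lay.rod_w.start, lay.rod_t.start, -1.0, phi)]
                if interior:
                    curv.append(("rank1", -k_att, u))
                yield idx, J, Ka, e, curv

        # weak 'surgeon grip' on the rod: regularizes the otherwise free
        # axial-sliding and roll modes of the cylindrical joints
        if self.rod is not None and self.attach_scale > 0.0:
            Kg = np.array([st.rod_hold_translation] * 3)
            psi_r = log_so3(state.rod_R)
            Kgr = np.array([st.rod_hold_rotation] * 3)
            if need_jac:
                yield self._idx_rod_t, _EYE3.copy(), Kg, state.rod_t.copy(), []
                yield self._idx_rod_w, left_jacobian_inv(psi_r), Kgr, psi_r, []
            else:
                yield self._idx_rod_t, None, Kg, state.rod_t, None
                yield self._idx_rod_w, None, Kgr, psi_r, None

        # derotation drive on the rod plane normal
        if self.rod is not None and self.drive_target is not None:
            n = self.rod_plane_normal(state)
            e = n - self.drive_target
            Kd = np.array([st.k_drive] * 3)
            if need_jac:
                yield (self._idx_rod_w, -skew(n), Kd, e,
                       [("rot3", lay.rod_w.start, n, _EYE3)])
            else:
                yield self._idx_rod_w, None, Kd, e, None

        # compression / distraction between two implants
        if self.compdist is not None:
            ka, kb, target = self.compdist
            d = state.h[kb] - state.h[ka]
            dist = float(np.linalg.norm(d))
            u = d / dist
            idx = np.r_[np.arange(lay.imp(ka).start, lay.imp(ka).stop),
                        np.arange(lay.imp(kb).start, lay.imp(kb).stop)]
            Kc = np.array([st.k_compdist])
            e = np.array([dist - target])
            if need_jac:
                J = np.concatenate([-u, u])[None, :]
                yield (idx, J, Kc, e,
                       [("dist", lay.imp(ka).start, lay.imp(kb).start, u, dist)])
            else:
                yield idx, None, Kc, e, None

    def assemble(self, state: _State | None = None):
        """Gradient, Gauss-Newton Hessian, geometric-stiffness correction
        and characteristic force at a state."""
        state = state or self.state
        n = self.layout.n_dof
        g = np.zeros(n)
        H = np.zeros((n, n))
        C = np.zeros((n, n))
        char2 = 1.0
        ix_cache = self._ix_cache
        for idx, J, K, e, curv in self._terms(state):
            f = K * e
            g[idx] += J.T @ f
            ix = ix_cache.get(id(idx))
            if ix is None:
                ix = np.ix_(idx, idx)
            H[ix] += J.T @ (K[:, None] * J)
            char2 = max(char2, float(f @ f))
            for item in curv:
                if item[0] == "rot3":
                    _, j0, u, AT = item
                    phi = AT @ f
                    up = u[:, None] * phi[None, :]
                    G = 0.5 * (up + up.T) - (u @ phi) * _EYE3
                    C[j0 : j0 + 3, j0 : j0 + 3] += G
                elif item[0] == "alpha":
                    _, j0, u, AT = item
                    phi = AT @ f
                    C[j0, j0] += (phi @ _Y) * (u @ _Y) - u @ phi
                elif item[0] == "rank1":
                    _, coeff, ehat = item
                    v = J.T @ ehat
                    ixc = ix_cache.get(id(idx))
                    if ixc is None:
                        ixc = np.ix_(idx, idx)
                    C[ixc] += coeff * (v[:, None] * v[None, :])
                elif item[0] == "cross":
                    _, jw, jt, sgn, phi = item
                    S = sgn * skew(phi)
                    C[jw : jw + 3, jt : jt + 3] += S
                    C[jt : jt + 3, jw : jw + 3] += S.T
                else:  # 'dist'
                    _, ja, jb, u, dist = item
                    P = (_EYE3 - np.outer(u, u)) * (float(f[0]) / dist)
                    C[ja : ja + 3, ja : ja + 3] += P
                    C[jb : jb + 3, jb : jb + 3] += P
                    C[ja : ja + 3, jb : jb + 3] -= P
                    C[jb : jb + 3, ja : ja + 3] -= P
        for vi, fext in self.external_loads:
            g[self.layout.vert_t(vi)] -= fext
            char2 = max(char2, float(fext @ fext))
        return g, H, C, float(np.sqrt(char2))

    def energy(self, state: _State | None = None) -> float:
        """Total elastic potential energy (exact, incl. the piecewise
        quadratic implant-link law); used by the solver line search."""
        state = state or self.state
        E = 0.0
        n_link0 = 2 * self.n_joints + 1
        for ne, (idx, _J, K, e, _curv) in enumerate(self._terms(state, need_jac=False)):
            if n_link0 <= ne < n_link0 + len(self.implants):
                imp = self.implants[ne - n_link0]
                m = float(np.sqrt(e @ e))
                d0 = imp["delta0"]
                if m <= d0:
                    E += 0.5 * imp["k1"] * m * m
                else:
                    E += (0.5 * imp["k1"] * d0 * d0
                          + imp["k1"] * d0 * (m - d0)
                          + 0.5 * imp["k2"] * (m - d0) ** 2)
            else:
                E += 0.5 * float(e @ (K * e))
        for vi, fext in self.external_loads:
            E -= float(fext @ state.t[vi])
        return E

    # -- extraction ---------------------------------------------------------

    def extract_spine(self, state: _State | None = None) -> SpineModel:
        state = state or self.state
        verts = []
        for i, lab in enumerate(self.labels):
            v0 = self.spine0[lab]
            pts = (v0.points() - self.c0[i]) @ state.R[i].T + self.c0[i] + state.t[i]
            verts.append(VertebraGeom.from_points(lab, pts))
        vp = self.spine0["PELVIS"]
        Rp = exp_so3(state.alpha * _Y)
        pts = (vp.points() - self.pelvis_c0) @ Rp.T + self.pelvis_c0
        verts.append(VertebraGeom.from_points("PELVIS", pts))
        return SpineModel(verts)

    def seating_gaps(self) -> np.ndarray:
        """Implant-to-rod seating distances (mm)."""
        ow, Rw = self.rod_world(self.state)
        gaps = []
        for k in range(len(self.implants)):
            hprime = Rw.T @ (self.state.h[k] - ow)
            foot, _u, _interior = self._closest_on_rod(hprime)
            gaps.append(float(np.linalg.norm(hprime - foot)))
        return np.array(gaps)


def build_model(spine: SpineModel, config: InstrumentationConfig,
                stiffness_cfg: StiffnessConfig | None = None) -> FlexSpineModel:
    """Assemble the multibody model for a strategy on a patient geometry.

    Boundary conditions: all pelvis degrees of freedom are fixed except
    sagittal-plane rotation; T1 translates freely and rotates freely in the
    frontal plane (its other rotations carry weak restraining springs).
    At zero load the reference configuration is stress-free."""
    config.validate()
    spine.validate()
    return FlexSpineModel(spine, config, stiffness_cfg or StiffnessConfig())


# ---------------------------------------------------------------------------
# Equilibrium solver
# ---------------------------------------------------------------------------

def solve_equilibrium(model: FlexSpineModel, loads: dict[str, Sequence[float]] | None = None,
                      max_newton: int | None = None) -> dict:
    """Damped Newton iteration to generalized force balance.

    ``loads``: optional {vertebra label: 3-force (N)} applied at body
    centers.  Success when the scaled residual norm drops below
    rtol x characteristic load; raises :class:`SimulationError` otherwise.
    Returns a log dict (iterations, residual, tolerance)."""
    if loads is not None:
        model.external_loads = [(level_index(lab), np.asarray(f, dtype=float))
                                for lab, f in loads.items()]
    st = model.stiffness
    max_newton = max_newton or st.max_newton
    act = model.layout.active_indices()
    gs = model._gscale

    E = model.energy()
    last_res = np.inf
    lam_lm = 1e-4
    n_act = len(act)

    for it in range(max_newton + 1):
        g, H, C, char = model.assemble()
        res = float(np.max(np.abs(g[act] * gs[act])))
        tol = st.rtol * char
        last_res = res
        if res <= tol:
            return {"iterations": it, "residual": res, "tolerance": tol}
        ga = g[act]
        Hfull = (H + C)[np.ix_(act, act)]
        D = np.abs(np.diag(H[np.ix_(act, act)])) + 1e-6
        # Levenberg-Marquardt damping: regularizes the flat sliding modes of
        # the cylindrical joints and any indefiniteness of the geometric
        # stiffness, and vanishes near the solution (quadratic convergence)
        accepted = False
        for _ in range(25):
            A = Hfull + lam_lm * np.diag(D)
            try:
                step = np.linalg.solve(A, -ga)
            except np.linalg.LinAlgError:
                lam_lm *= 8.0
                continue
            if not np.all(np.isfinite(step)) or ga @ step >= 0:
                lam_lm *= 8.0
                continue
            delta = np.zeros(model.layout.n_dof)
            delta[act] = step
            trial = model.state.copy()
            trial.apply(delta, model.layout)
            Et = model.energy(trial)
            if Et <= E + 1e-12 * (abs(E) + 1.0):
                model.state = trial
                E = Et
                lam_lm = max(lam_lm / 3.0, 1e-12)
                accepted = True
                break
            lam_lm *= 8.0
        if not accepted:
            break
    raise SimulationError(
        f"equilibrium not reached: residual {last_res:.3e} after {max_newton} iterations")


def tangent_system(model: FlexSpineModel):
    """Active-set gradient and tangent stiffness at the current state
    (the linearization K used by the small-load oracle)."""
    g, H, C, _ = model.assemble()
    act = model.layout.active_indices()
    return g[act], (H + C)[np.ix_(act, act)], act


# ---------------------------------------------------------------------------
# Manoeuvres
# ---------------------------------------------------------------------------

def _maneuver_attach(model: FlexSpineModel, rod: RodGeometry, params: dict) -> list:
    log = []
    if model.rod is None:
        model.set_rod(rod)
    for gamma in model.stiffness.attach_ramp:
        model.attach_scale = gamma
        info = solve_equilibrium(model)
        log.append({"maneuver": "attach", "ramp": gamma, **info})
    gaps = model.seating_gaps()
    if float(gaps.max()) > 0.5:
        raise ManeuverError(
            f"seating distance not closing: max implant-rod gap {gaps.max():.2f} mm")
    log[-1]["max_gap_mm"] = float(gaps.max())
    return log


def _maneuver_derotate(model: FlexSpineModel, params: dict) -> list:
    if model.rod is None:
        raise ManeuverError("derotation requires an attached rod")
    tol_deg = float(params.get("tolerance", 0.5))
    st = model.stiffness
    log = []
    n0 = model.rod_plane_normal()
    sigma = 1.0 if n0 @ _Y >= 0 else -1.0
    target_candidates = []
    v0 = (model.state.rod_R @ model.rod.R0)[:, 0]
    for sg in (sigma, -sigma):
        nt = sg * _Y
        axis = np.cross(n0, nt)
        ang = float(np.arccos(np.clip(n0 @ nt, -1.0, 1.0)))
        if np.linalg.norm(axis) < 1e-12:
            score = v0 @ (-_X)
        else:
            Rg = exp_so3(axis / np.linalg.norm(axis) * ang)
            score = (Rg @ v0) @ (-_X)
        target_candidates.append((score, sg, ang))
    # rotate so the thoracic bulge ends posterior (kyphotic direction)
    _, sg, total = max(target_candidates, key=lambda t: t[0])
    n_target = sg * _Y
    axis = np.cross(n0, n_target)
    if np.linalg.norm(axis) < 1e-12:
        axis = np.cross(n0, _X)
    axis = axis / np.linalg.norm(axis)

    n_steps = max(1, int(np.ceil(np.degrees(total) / st.derot_step_deg)))
    for k in range(1, n_steps + 1):
        frac = k / n_steps
        model.drive_target = exp_so3(axis * (total * frac)) @ n0
        info = solve_equilibrium(model)
        log.append({"maneuver": "derotate", "fraction": frac, **info})
    model.drive_target = n_target
    info = solve_equilibrium(model)
    n_final = model.rod_plane_normal()
    plane_angle = float(np.degrees(np.arccos(np.clip(abs(n_final @ _Y), -1.0, 1.0))))
    if plane_angle > tol_deg:
        raise ManeuverError(
            f"derotation stalled: rod plane {plane_angle:.2f} deg from sagittal")
    log.append({"maneuver": "derotate", "fraction": 1.0,
                "plane_angle_deg": plane_angle, **info})
    return log


def _maneuver_compdist(model: FlexSpineModel, kind: str, params: dict) -> list:
    la, lb = params["implants"]
    ks = [k for k, imp in enumerate(model.implants) if imp["level"] in (la, lb)]
    if len(ks) != 2:
        raise ManeuverError(f"{kind}: implants {la}/{lb} not present")
    ka, kb = ks
    d0 = float(np.linalg.norm(model.state.h[kb] - model.state.h[ka]))
    target = float(params.get("target", d0))
    log = []
    if abs(target - d0) < 1e-9:
        model.compdist = None
        return [{"maneuver": kind, "target_mm": target, "iterations": 0,
                 "residual": 0.0, "note": "already at target"}]
    for frac in (0.25, 0.5, 0.75, 1.0):
        model.compdist = (ka, kb, d0 + (target - d0) * frac)
        info = solve_equilibrium(model)
        log.append({"maneuver": kind, "fraction": frac, **info})
    dist = float(np.linalg.norm(model.state.h[kb] - model.state.h[ka]))
    log[-1]["separation_mm"] = dist
    return log


def apply_maneuver(model: FlexSpineModel, rod: RodGeometry | None,
                   step: tuple[str, dict]) -> list:
    """Execute one manoeuvre step and return its log entries."""
    kind, params = step
    if kind == "attach":
        if rod is None:
            raise ManeuverError("attach requires a rod geometry")
        return _maneuver_attach(model, rod, params)
    if kind == "derotate":
        return _maneuver_derotate(model, params)
    if kind in ("compress", "distract"):
        return _maneuver_compdist(model, kind, params)
    raise ValidationError(f"unknown maneuver {kind!r}")


def run_instrumentation(spine: SpineModel, config: InstrumentationConfig,
                        stiffness_cfg: StiffnessConfig | None = None,
                        segments: dict[str, SegmentDef] | None = None) -> SimResult:
    """Simulate a full instrumentation strategy on a patient geometry.

    Builds the model, contours the rod, runs the manoeuvre sequence
    (default: attach, then derotate), solves the final equilibrium and
    measures the postoperative descriptors with the unfused count from the
    configuration.  Deterministic.  A non-convergent configuration is
    returned with ``converged=False`` rather than raised."""
    model = build_model(spine, config, stiffness_cfg)
    rod = shape_rod(config, spine, model.stiffness)
    log: list = []
    try:
        for step in config.maneuver_sequence:
            log.extend(apply_maneuver(model, rod, step))
        final = solve_equilibrium(model)
        log.append({"maneuver": "final", **final})
        post = model.extract_spine()
        post.validate()
        desc = compute_all(post, segments=segments, config=(config.uiv, config.liv))
        return SimResult(post_model=post, post_descriptors=desc, converged=True,
                         residual=float(final["residual"]), maneuver_log=log)
    except (SimulationError, ManeuverError, ValidationError) as exc:
        log.append({"maneuver": "abort", "error": str(exc)})
        post = model.extract_spine()
        return SimResult(post_model=post, post_descriptors=None, converged=False,
                         residual=float("nan"), maneuver_log=log)
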