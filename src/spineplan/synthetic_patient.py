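"""Parametric generator of 3D scoliotic spine geometries.

The generator emulates a landmark reconstruction of a thoracic/lumbar spine:
vertebral body centers are placed at anthropometric stations along a
deformable centerline, endplate and pedicle landmarks are offset from each
center in a local frame that follows the centerline tangent and an imposed
axial-rotation profile.

Deformity parameterization
--------------------------
* Coronal plane: one half-sine lateral deflection per named curve region
  (PT, MT, TL/L) — zero at the end (neutral) vertebrae, extremum at the apex,
  sign by convexity side (+y = patient-left).  The half-sine makes the end
  vertebrae inflexion points of the coronal projection, matching how Cobb
  segments are defined.
* Sagittal plane: a posterior (kyphotic) bow spanning T4-T12 and an anterior
  (lordotic) bow spanning T12-L5.
* Transverse plane: per-region axial rotation, a half-sine peaking at the
  apex with the specified apical value.

A fixed-point calibration loop rescales the five amplitude parameters until
downstream Cobb/kyphosis/lordosis measurements hit requested targets, which
is how the packaged index patient (Lenke 2B; PT 51 deg left, MT 56 deg right,
TL/L 38 deg left, TK 22 deg, LL 44 deg) is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .spine_geometry import (
    LEVELS,
    SPINE_LEVELS,
    SpineModel,
    SpinePlanError,
    ValidationError,
    VertebraGeom,
    level_index,
)

__all__ = [
    "CurveSpec",
    "PatientParams",
    "CalibrationError",
    "build_centerline",
    "generate_spine",
    "calibrate_to_targets",
    "index_patient_params",
    "index_patient_fixture",
    "index_patient_targets",
    "load_patient_params",
    "save_patient_params",
]

_DATA_DIR = Path(__file__).parent / "data"

#: Printed preoperative measures of the packaged index patient (degrees).
INDEX_TARGETS: dict[str, float] = {"PT": 51.0, "MT": 56.0, "TL/L": 38.0,
                                   "TK": 22.0, "LL": 44.0}


class CalibrationError(SpinePlanError):
    """The fixed-point amplitude calibration did not reach its targets."""


# center-to-center stations, mm, before scaling to total_height (T1->pelvis)
_SPACING = {
    "T2": 19.0, "T3": 20.0, "T4": 20.0, "T5": 21.0, "T6": 21.0, "T7": 22.0,
    "T8": 22.0, "T9": 23.0, "T10": 24.0, "T11": 25.0, "T12": 26.0,
    "L1": 27.0, "L2": 28.0, "L3": 29.0, "L4": 29.0, "L5": 30.0,
    "PELVIS": 40.0,
}
_TOTAL_SPAN = sum(_SPACING.values())  # 426 mm nominal


@dataclass
class CurveSpec:
    """One scoliotic curve region."""

    region: str                  # "PT" | "MT" | "TL/L"
    upper_end: str
    apex: str
    lower_end: str
    coronal_amplitude: float     # mm, >= 0
    side: str                    # "left" | "right"
    apical_axial_rotation: float = 0.0  # degrees, |.| <= 45

    def validate(self) -> None:
        if self.region not in ("PT", "MT", "TL/L"):
            raise ValidationError(f"unknown curve region {self.region!r}")
        iu, ia, il = (level_index(l) for l in (self.upper_end, self.apex, self.lower_end))
        if not iu < ia < il:
            raise ValidationError(
                f"{self.region}: apex {self.apex} must lie strictly between "
                f"{self.upper_end} and {self.lower_end}")
        if self.coronal_amplitude < 0:
            raise ValidationError(f"{self.region}: negative coronal amplitude")
        if self.side not in ("left", "right"):
            raise ValidationError(f"{self.region}: side must be left or right")
        if abs(self.apical_axial_rotation) > 45.0:
            raise ValidationError(f"{self.region}: |apical axial rotation| > 45 deg")

    @property
    def signed_amplitude(self) -> float:
        """Amplitude with the sign convention +y = patient-left."""
        return self.coronal_amplitude if self.side == "left" else -self.coronal_amplitude


@dataclass
class PatientParams:
    """Full parameter set for one synthetic patient."""

    curves: list[CurveSpec]
    kyphosis_amplitude: float = 17.0    # mm posterior bow, T4-T12
    lordosis_amplitude: float = 25.0    # mm anterior bow, T12-L5
    total_height: float = 430.0         # mm, T1 center to pelvis center
    seed: int = 0
    jitter_sigma: float = 0.0           # mm, optional landmark noise (default off)

    def validate(self) -> None:
        if not 350.0 <= self.total_height <= 550.0:
            raise ValidationError("total_height outside [350, 550] mm")
        if len(self.curves) != 3:
            raise ValidationError("expected three curve regions (PT, MT, TL/L)")
        for c in self.curves:
            c.validate()
        order = sorted(self.curves, key=lambda c: level_index(c.upper_end))
        for a, b in zip(order, order[1:]):
            ia_low = level_index(a.lower_end)
            ib_up = level_index(b.upper_end)
            if ia_low > ib_up:
                raise ValidationError(
                    f"curve regions {a.region} and {b.region} overlap")
            if ia_low != ib_up:
                raise ValidationError(
                    f"adjacent curves {a.region}/{b.region} must share an end vertebra")
        # sagittal bow amplitudes are signed: positive = conventional
        # kyphotic (posterior) / lordotic (anterior) direction
        if abs(self.kyphosis_amplitude) > 150 or abs(self.lordosis_amplitude) > 150:
            raise ValidationError("sagittal bow amplitudes must be within 150 mm")

    def curve(self, region: str) -> CurveSpec:
        for c in self.curves:
            if c.region == region:
                return c
        raise ValidationError(f"no curve region {region!r}")


def stations(params: PatientParams) -> dict[str, float]:
    """z-coordinate (mm) of each body center; pelvis at 0, T1 at total_height."""
    scale = params.total_height / _TOTAL_SPAN
    z: dict[str, float] = {}
    acc = params.total_height
    z["T1"] = acc
    for label in LEVELS[1:]:
        acc -= _SPACING[label] * scale
        z[label] = acc
    return z


def _bump(t: float, ta: float) -> float:
    """Half-sine with apex at ta: 0 at t=0,1; 1 at t=ta; C1 at the apex."""
    if t <= 0.0 or t >= 1.0:
        return 0.0
    if t <= ta:
        return float(np.sin(0.5 * np.pi * t / ta))
    return float(np.sin(0.5 * np.pi * (1.0 - t) / (1.0 - ta)))


def _dbump(t: float, ta: float) -> float:
    """d/dt of :func:`_bump` (one-sided interior limit at the region ends)."""
    if t < 0.0 or t > 1.0:
        return 0.0
    if t <= ta:
        return float(0.5 * np.pi / ta * np.cos(0.5 * np.pi * t / ta))
    return float(-0.5 * np.pi / (1.0 - ta) * np.cos(0.5 * np.pi * (1.0 - t) / (1.0 - ta)))


class _Deflection:
    """Lateral (y) and sagittal (x) deflection profiles as functions of z.

    Each profile is a natural C2 cubic spline through deformity control
    points: zero deflection at the neutral (end) vertebrae of every curve
    region and the signed amplitude at each apex; the sagittal profile pins
    zero at T1/T4/T12/L5/pelvis with the kyphotic (posterior, -x) and
    lordotic (anterior, +x) apexes at the bow midpoints.  The spline basis
    keeps the centerline C2-continuous so the neutral vertebrae are clean
    inflexion points of the coronal projection."""

    def __init__(self, params: PatientParams):
        from scipy.interpolate import CubicSpline

        z = stations(params)
        self._lateral = self._fit_coronal(params, z)

        sag_inside: set[str] = set()
        if params.kyphosis_amplitude != 0.0:
            sag_inside.update(LEVELS[level_index("T4") + 1 : level_index("T12")])
        if params.lordosis_amplitude != 0.0:
            sag_inside.update(LEVELS[level_index("T12") + 1 : level_index("L5")])
        sag_nodes = {z[l]: 0.0 for l in LEVELS if l not in sag_inside}
        if params.kyphosis_amplitude != 0.0:
            sag_nodes[0.5 * (z["T4"] + z["T12"])] = -params.kyphosis_amplitude
        if params.lordosis_amplitude != 0.0:
            sag_nodes[0.5 * (z["T12"] + z["L5"])] = +params.lordosis_amplitude
        self._anterior = self._fit(sag_nodes)

        self.rotation = []  # (z_upper, z_apex, z_lower, apical rotation deg)
        for c in params.curves:
            self.rotation.append((z[c.upper_end], z[c.apex], z[c.lower_end],
                                  c.apical_axial_rotation))

    @staticmethod
    def _fit(nodes: dict[float, float]):
        from scipy.interpolate import CubicSpline

        zs = np.array(sorted(nodes))
        vals = np.array([nodes[zq] for zq in zs])
        return CubicSpline(zs, vals, bc_type="natural")

    @staticmethod
    def _fit_coronal(params: "PatientParams", z: dict[str, float]):
        """C1 Hermite coronal profile with controlled end tangents.

        Each curve region contributes zero deflection at its end (neutral)
        vertebrae and the signed amplitude at its apex.  The tangent angles
        at the neutral nodes are chosen so the tangent-angle drop across
        region i equals the region's own amplitude-implied Cobb
        w_i = 2 atan(pi A_i / (2 L_i)): with alternating convexities the
        shared tangents (a, b, c, d) at the four boundary nodes satisfy
        a+b = w1, b+c = w2, c+d = w3, and the leftover degree of freedom
        minimizes the end-to-end imbalance.  This decouples adjacent Cobb
        angles, so each is a monotone function of its own amplitude alone.
        """
        from scipy.interpolate import CubicHermiteSpline

        regions = sorted(params.curves, key=lambda c: level_index(c.upper_end))
        # boundary nodes in cephalocaudal order: upper end of the first
        # region, then each region's lower end (shared with the next)
        node_labels = [regions[0].upper_end] + [c.lower_end for c in regions]
        rows = []
        wants = []
        for i, c in enumerate(regions):
            if c.coronal_amplitude == 0.0:
                continue
            L = z[c.upper_end] - z[c.lower_end]
            sigma = 1.0 if c.side == "left" else -1.0
            row = np.zeros(len(node_labels))
            row[i] = -sigma       # upper-end tangent angle
            row[i + 1] = +sigma   # lower-end tangent angle
            rows.append(row)
            wants.append(2.0 * np.arctan(np.pi * c.coronal_amplitude / (2.0 * L)))
        if rows:
            A = np.vstack(rows)
            theta = A.T @ np.linalg.solve(A @ A.T, np.array(wants))
        else:
            theta = np.zeros(len(node_labels))
        boundary_slopes = {z[lab]: float(np.tan(t))
                           for lab, t in zip(node_labels, theta)}

        inside: set[str] = set()
        for c in regions:
            if c.coronal_amplitude == 0.0:
                continue
            iu, il = level_index(c.upper_end), level_index(c.lower_end)
            inside.update(LEVELS[iu + 1 : il])
        nodes: dict[float, tuple[float, float]] = {}
        for lab in LEVELS:
            if lab not in inside:
                nodes[z[lab]] = (0.0, boundary_slopes.get(z[lab], 0.0))
        for c in regions:
            if c.coronal_amplitude > 0.0:
                nodes[z[c.apex]] = (c.signed_amplitude, 0.0)
        zs = np.array(sorted(nodes))
        vals = np.array([nodes[zq][0] for zq in zs])
        slopes = np.array([nodes[zq][1] for zq in zs])
        return CubicHermiteSpline(zs, vals, slopes)

    def lateral(self, zq: float) -> tuple[float, float]:
        """Deflection (mm) and slope d/dz at height zq."""
        return float(self._lateral(zq)), float(self._lateral(zq, 1))

    def anterior(self, zq: float) -> tuple[float, float]:
        return float(self._anterior(zq)), float(self._anterior(zq, 1))

    def axial(self, zq: float) -> float:
        val = 0.0
        for zu, za, zl, amp in self.rotation:
            if zl < zq < zu:
                span = zu - zl
                t = (zu - zq) / span
                ta = (zu - za) / span
                val += amp * _bump(t, ta)
            elif zq == za:
                val += amp
        return val


def build_centerline(params: PatientParams, n_samples: int = 200) -> np.ndarray:
    """Sampled 3D spinal centerline (ordered cephalad to caudal, mm).

    The curve runs from the T1 station down to the pelvis station; z is
    strictly decreasing, x and y carry the sagittal and coronal deflections.
    """
    params.validate()
    defl = _Deflection(params)
    zs = np.linspace(params.total_height, 0.0, n_samples)
    pts = np.empty((n_samples, 3))
    for i, zq in enumerate(zs):
        x, _ = defl.anterior(zq)
        y, _ = defl.lateral(zq)
        pts[i] = (x, y, zq)
    return pts


# per-level vertebral body dimensions, mm, linear in anatomical position
def _dims(label: str) -> tuple[float, float, float]:
    """(width y, depth x, body height z) of the vertebral body."""
    i = level_index(label)
    f = i / 16.0  # 0 at T1, 1 at L5
    width = 28.0 + 17.0 * f
    depth = 22.0 + 12.0 * f
    height = 13.0 + 8.0 * f
    return width, depth, height


def generate_spine(params: PatientParams) -> SpineModel:
    """Place 17 vertebrae plus the pelvis along the deformed centerline.

    Local z follows the centerline tangent, local y starts from global +y
    (orthogonalized) and is then rotated about local z by the region's axial
    rotation profile.  Deterministic given params; ``seed`` only drives the
    optional Gaussian landmark jitter (``jitter_sigma``, default 0).
    """
    params.validate()
    defl = _Deflection(params)
    z_of = stations(params)
    rng = np.random.default_rng(params.seed)

    vertebrae = []
    for label in SPINE_LEVELS:
        zq = z_of[label]
        x, dxdz = defl.anterior(zq)
        y, dydz = defl.lateral(zq)
        center = np.array([x, y, zq])
        zax = np.array([dxdz, dydz, 1.0])
        zax /= np.linalg.norm(zax)
        yax = np.array([0.0, 1.0, 0.0])
        yax = yax - (yax @ zax) * zax
        yax /= np.linalg.norm(yax)
        xax = np.cross(yax, zax)
        # the rotation parameter is defined in the transverse plane (what the
        # pedicle-projection method measures); solve for the local rotation
        # that projects to the requested angle, cancelling tilt artefacts
        phi = np.deg2rad(defl.axial(zq))
        num = yax[0] * np.cos(phi) + yax[1] * np.sin(phi)
        den = xax[0] * np.cos(phi) + xax[1] * np.sin(phi)
        rho = np.arctan2(num, den) if (abs(num) > 1e-15 or phi != 0.0) else 0.0
        c, s = np.cos(rho), np.sin(rho)
        xr = c * xax + s * yax
        yr = -s * xax + c * yax
        vertebrae.append(_make_vertebra(label, center, xr, yr, zax))

    vertebrae.append(_make_pelvis())

    if params.jitter_sigma > 0:
        jittered = []
        for v in vertebrae:
            pts = v.points() + rng.normal(0.0, params.jitter_sigma, size=(13, 3))
            jittered.append(VertebraGeom.from_points(v.label, pts))
        vertebrae = jittered

    model = SpineModel(vertebrae)
    model.validate()
    return model


def _make_vertebra(label: str, center: np.ndarray, x: np.ndarray,
                   y: np.ndarray, z: np.ndarray) -> VertebraGeom:
    w, d, h = _dims(label)
    sup = center + 0.5 * h * z
    inf = center - 0.5 * h * z
    corners = []
    for ec in (sup, inf):
        corners.append(np.vstack([
            ec + 0.5 * d * x + 0.5 * w * y,
            ec + 0.5 * d * x - 0.5 * w * y,
            ec - 0.5 * d * x - 0.5 * w * y,
            ec - 0.5 * d * x + 0.5 * w * y,
        ]))
    ped_off_x = -(0.5 * d + 6.0)
    ped_off_y = 0.35 * w + 3.0
    return VertebraGeom(
        label=label,
        body_center=center,
        sup_endplate_center=sup,
        inf_endplate_center=inf,
        sup_endplate_corners=corners[0],
        inf_endplate_corners=corners[1],
        left_pedicle=center + ped_off_x * x + ped_off_y * y,
        right_pedicle=center + ped_off_x * x - ped_off_y * y,
    )


def _make_pelvis() -> VertebraGeom:
    e3 = np.eye(3)
    return _pelvis_from_axes(np.zeros(3), e3[0], e3[1], e3[2])


def _pelvis_from_axes(center, x, y, z) -> VertebraGeom:
    sup = center + 18.0 * z
    inf = center - 18.0 * z
    corners = []
    for ec in (sup, inf):
        corners.append(np.vstack([
            ec + 30.0 * x + 40.0 * y,
            ec + 30.0 * x - 40.0 * y,
            ec - 30.0 * x - 40.0 * y,
            ec - 30.0 * x + 40.0 * y,
        ]))
    return VertebraGeom(
        label="PELVIS", body_center=center,
        sup_endplate_center=sup, inf_endplate_center=inf,
        sup_endplate_corners=corners[0], inf_endplate_corners=corners[1],
        left_pedicle=center - 45.0 * x + 40.0 * y,
        right_pedicle=center - 45.0 * x - 40.0 * y,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_AMPLITUDE_CAP = 150.0  # mm; beyond this the half-sine model is meaningless


def _measure(params: PatientParams) -> dict[str, float]:
    from . import descriptors as D

    model = generate_spine(params)
    segs = D.segments_from_params(params)
    out = {}
    for region in ("PT", "MT", "TL/L"):
        angle, _side = D.coronal_cobb(model, segs[region])
        out[region] = angle
    out["TK"] = D.sagittal_cobb(model, segs["TK"])
    out["LL"] = D.sagittal_cobb(model, segs["LL"])
    return out


def calibrate_to_targets(params: PatientParams, targets: dict[str, float],
                         tol: float = 0.5, max_iter: int = 25) -> PatientParams:
    """Rescale deformity amplitudes until measured angles hit the targets.

    Fixed-point sweeps: each amplitude is multiplied by target/measured until
    every requested measure (subset of PT, MT, TL/L Cobb; TK; LL, degrees)
    agrees within ``tol``.  Deterministic.  Raises :class:`CalibrationError`
    with the residuals if ``max_iter`` sweeps do not converge.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    unknown = set(targets) - {"PT", "MT", "TL/L", "TK", "LL"}
    if unknown:
        raise ValidationError(f"unknown calibration targets {sorted(unknown)}")
    params.validate()
    cur = replace(params, curves=[replace(c) for c in params.curves])

    def _get(key: str) -> float:
        if key in ("PT", "MT", "TL/L"):
            return cur.curve(key).coronal_amplitude
        return cur.kyphosis_amplitude if key == "TK" else cur.lordosis_amplitude

    def _set(key: str, value: float) -> None:
        if key in ("PT", "MT", "TL/L"):
            # keep a targeted curve strictly active: at zero amplitude the
            # region releases its end-tangent constraint, which makes the
            # measured Cobb discontinuous in the amplitude
            cur.curve(key).coronal_amplitude = float(np.clip(value, 0.5, _AMPLITUDE_CAP))
        elif key == "TK":
            cur.kyphosis_amplitude = float(np.clip(value, -_AMPLITUDE_CAP, _AMPLITUDE_CAP))
        else:
            cur.lordosis_amplitude = float(np.clip(value, -_AMPLITUDE_CAP, _AMPLITUDE_CAP))

    history: dict[str, tuple[float, float]] = {}
    for sweep in range(max_iter):
        try:
            measured = _measure(cur)
        except ValidationError as exc:
            raise CalibrationError(
                f"calibration left the feasible geometry range: {exc}") from exc
        resid = {k: measured[k] - v for k, v in targets.items()}
        if all(abs(r) <= tol for r in resid.values()):
            return cur
        for key, target in targets.items():
            got = measured[key]
            amp = _get(key)
            # damped secant per parameter: robust to the residual coupling
            # between adjacent coronal curves and between the two sagittal
            # bows (which share the T12 tangent)
            prev = history.get(key)
            slope = None
            if prev is not None and abs(amp - prev[0]) > 1e-12:
                slope = (got - prev[1]) / (amp - prev[0])
            if slope is None or abs(slope) < 0.05:
                slope = 1.0  # deg per mm, order-of-magnitude prior
            step = float(np.clip((target - got) / slope, -30.0, 30.0))
            history[key] = (amp, got)
            _set(key, amp + step)
    measured = _measure(cur)
    resid = {k: measured[k] - v for k, v in targets.items()}
    if all(abs(r) <= tol for r in resid.values()):
        return cur
    raise CalibrationError(
        f"calibration did not converge in {max_iter} sweeps; residuals (deg): "
        + ", ".join(f"{k}={v:+.2f}" for k, v in resid.items()))


# ---------------------------------------------------------------------------
# Packaged index patient
# ---------------------------------------------------------------------------

def load_patient_params(path: str | Path) -> tuple[PatientParams, dict[str, float]]:
    """Read a patient parameter file (YAML); returns (params, targets).

    ``targets`` is the optional calibration-target block ({} if absent)."""
    doc = yaml.safe_load(Path(path).read_text())
    curves = [CurveSpec(
        region=c["region"], upper_end=c["upper_end"], apex=c["apex"],
        lower_end=c["lower_end"], coronal_amplitude=float(c["coronal_amplitude"]),
        side=c["side"], apical_axial_rotation=float(c.get("apical_axial_rotation", 0.0)),
    ) for c in doc["curves"]]
    params = PatientParams(
        curves=curves,
        kyphosis_amplitude=float(doc.get("kyphosis_amplitude", 17.0)),
        lordosis_amplitude=float(doc.get("lordosis_amplitude", 25.0)),
        total_height=float(doc.get("total_height", 430.0)),
        seed=int(doc.get("seed", 0)),
        jitter_sigma=float(doc.get("jitter_sigma", 0.0)),
    )
    params.validate()
    targets = {str(k): float(v) for k, v in (doc.get("targets") or {}).items()}
    return params, targets


def save_patient_params(params: PatientParams, path: str | Path,
                        targets: dict[str, float] | None = None) -> None:
    params.validate()
    doc = {
        "total_height": params.total_height,
        "seed": params.seed,
        "jitter_sigma": params.jitter_sigma,
        "kyphosis_amplitude": params.kyphosis_amplitude,
        "lordosis_amplitude": params.lordosis_amplitude,
        "curves": [{
            "region": c.region, "upper_end": c.upper_end, "apex": c.apex,
            "lower_end": c.lower_end, "coronal_amplitude": c.coronal_amplitude,
            "side": c.side, "apical_axial_rotation": c.apical_axial_rotation,
        } for c in params.curves],
    }
    if targets:
        doc["targets"] = dict(targets)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def index_patient_params() -> tuple[PatientParams, dict[str, float]]:
    """Uncalibrated parameters and targets of the packaged index patient."""
    return load_patient_params(_DATA_DIR / "index_patient.yaml")


def index_patient_targets() -> dict[str, float]:
    return dict(INDEX_TARGETS)


_FIXTURE_CACHE: dict[str, SpineModel] = {}


def index_patient_fixture() -> SpineModel:
    """Calibrated preoperative index-patient geometry (deterministic).

    Lenke 2B double thoracic pattern: PT T1-T5 (apex T3, left), MT T5-T11
    (apex T8, right), TL/L T11-L4 (apex L2, left); MT apical axial rotation
    15 deg.  Calibrated so the measured PT/MT/TL-L Cobb, kyphosis and
    lordosis match 51/56/38/22/44 deg.
    """
    if "model" not in _FIXTURE_CACHE:
        params, targets = index_patient_params()
        calibrated = calibrate_to_targets(params, targets, tol=0.1, max_iter=60)
        _FIXTURE_CACHE["params"] = calibrated
        _FIXTURE_CACHE["model"] = generate_spine(calibrated)
    return _FIXTURE_CACHE["model"].copy()


def index_patient_calibrated_params() -> PatientParams:
    index_patient_fixture()
    return _FIXTURE_CACHE["params"]
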