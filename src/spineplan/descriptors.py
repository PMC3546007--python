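"""The 12 geometric deformity descriptors plus the unfused-vertebra count.

Measures follow standard radiographic practice, applied to 3D landmark
geometry:

* coronal Cobb angles (PT, MT, TL/L) between perpendiculars to the fitted
  spinal curve at the segment end (inflexion/neutral) vertebrae;
* apical vertebral translation (AVT, cm) of the main-curve apex from the
  plumb line dropped from the most cephalad modeled vertebra (T1, standing
  in for C7 since the model spans T1 to pelvis);
* sagittal Cobb angles: thoracic kyphosis between the superior endplate of
  T4 and the inferior endplate of T12, lumbar lordosis between the superior
  endplate of T12 and the inferior endplate of L5 (positive = kyphotic /
  lordotic respectively);
* apical vertebral rotation (Stokes pedicle method): transverse-plane angle
  of the right-to-left pedicle chord against the +y axis;
* orientation of the plane of maximum curvature (PMC): angle between the
  plane through a segment's end and apical body centers and the sagittal
  plane, folded to [0, 90] deg;
* F: number of unfused vertebrae among T1..L5 given an instrumentation span.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.interpolate import CubicSpline, PPoly, make_smoothing_spline

from .spine_geometry import (
    SPINE_LEVELS,
    GeometryError,
    SpineModel,
    ValidationError,
    level_index,
    levels_between,
)

__all__ = [
    "SegmentDef",
    "DescriptorSet",
    "default_segments",
    "find_inflexion_points",
    "coronal_cobb",
    "sagittal_cobb",
    "apical_translation",
    "stokes_avr",
    "pmc_orientation",
    "unfused_count",
    "compute_all",
]


@dataclass(frozen=True)
class SegmentDef:
    """A named spinal segment: end vertebrae plus (for coronal curves) apex."""

    name: str
    upper: str
    lower: str
    apex: str | None = None

    def __post_init__(self) -> None:
        if level_index(self.upper) >= level_index(self.lower):
            raise ValidationError(f"{self.name}: {self.upper} not above {self.lower}")
        if self.apex is not None and not (
                level_index(self.upper) < level_index(self.apex) < level_index(self.lower)):
            raise ValidationError(f"{self.name}: apex {self.apex} outside segment")


def default_segments() -> dict[str, SegmentDef]:
    """Segment boundaries of the packaged index patient (Lenke 2B pattern)."""
    return {
        "PT": SegmentDef("PT", "T1", "T5", apex="T3"),
        "MT": SegmentDef("MT", "T5", "T11", apex="T8"),
        "TL/L": SegmentDef("TL/L", "T11", "L4", apex="L2"),
        "TK": SegmentDef("TK", "T4", "T12"),
        "LL": SegmentDef("LL", "T12", "L5"),
    }


def segments_from_params(params) -> dict[str, SegmentDef]:
    """Segment definitions matching a synthetic patient's curve regions."""
    segs = {}
    for c in params.curves:
        segs[c.region] = SegmentDef(c.region, c.upper_end, c.lower_end, apex=c.apex)
    segs["TK"] = SegmentDef("TK", "T4", "T12")
    segs["LL"] = SegmentDef("LL", "T12", "L5")
    return segs


@dataclass
class DescriptorSet:
    """The 12 deformity measures plus the unfused count F.

    Coronal Cobb angles are non-negative magnitudes (deg); AVT is signed cm
    (+ = patient-left); TK/LL are signed deg (+ = kyphotic / lordotic); AVR
    values are signed axial rotations (deg); PMC orientations lie in
    [0, 90] deg (angle from the sagittal plane)."""

    theta_PT: float
    theta_MT: float
    theta_TLL: float
    X_AVT: float
    theta_TK: float
    theta_LL: float
    theta_AVR_PT: float
    theta_AVR_MT: float
    theta_AVR_TLL: float
    theta_PMC_PT: float
    theta_PMC_MT: float
    theta_PMC_TLL: float
    F: int = 17

    _ANGULAR = ("theta_PT", "theta_MT", "theta_TLL", "theta_TK", "theta_LL",
                "theta_AVR_PT", "theta_AVR_MT", "theta_AVR_TLL",
                "theta_PMC_PT", "theta_PMC_MT", "theta_PMC_TLL")

    def as_dict(self) -> dict[str, float]:
        d = {k: float(v) for k, v in asdict(self).items()}
        d["F"] = int(self.F)
        return d

    def validate(self) -> None:
        for name in ("theta_PT", "theta_MT", "theta_TLL"):
            v = getattr(self, name)
            if not 0.0 <= v <= 120.0:
                raise ValidationError(f"{name}={v:.1f} outside [0, 120] deg")
        for name in ("theta_PMC_PT", "theta_PMC_MT", "theta_PMC_TLL"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValidationError(f"{name}={v:.1f} outside [0, 90] deg")
        if not 0 <= self.F <= 17:
            raise ValidationError(f"F={self.F} outside [0, 17]")


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

def _coronal_spline(model: SpineModel, lam: float = 0.0):
    """Cubic (optionally smoothing) spline of coronal-projected body centers,
    parameterized by s = -z so the abscissa is increasing T1 -> L5."""
    centers = model.body_centers(SPINE_LEVELS)
    s = -centers[:, 2]
    y = centers[:, 1]
    if lam and lam > 0.0:
        bsp = make_smoothing_spline(s, y, lam=lam)
        return PPoly.from_spline(bsp.tck)
    return CubicSpline(s, y)


def find_inflexion_points(model: SpineModel, lam: float = 0.0,
                          prominence: float = 0.10) -> list[str]:
    """Vertebrae nearest the sign changes of the fitted coronal curvature.

    A curvature sign change is a strict local extremum of the fitted
    coronal slope, so the detector finds prominent slope extrema (peak
    prominence at least ``prominence`` times the slope range, which rejects
    the small oscillations an interpolating spline develops along straight
    stretches) and maps each to the nearest vertebra.  A straight spine
    returns an empty list; labels come back deduplicated in cephalocaudal
    order."""
    from scipy.signal import find_peaks

    centers = model.body_centers(SPINE_LEVELS)
    if len(centers) < 5:
        raise ValidationError("need at least 5 vertebrae")
    s = -centers[:, 2]
    ydat = centers[:, 1]
    if np.max(np.abs(ydat - ydat[0])) < 1e-9:
        return []
    spline = _coronal_spline(model, lam)
    grid = np.linspace(s[0], s[-1], 800)
    slope = spline.derivative(1)(grid)
    rng_slope = float(np.ptp(slope))
    if rng_slope < 1e-12:
        return []
    prom = prominence * rng_slope
    peaks = []
    for sgn in (1.0, -1.0):
        idx, _props = find_peaks(sgn * slope, prominence=prom)
        peaks.extend(grid[idx])
    # snap each extremum to the nearest laterally neutral vertebra (on the
    # T1-L5 chord); an interpolating spline places the slope extremum
    # slightly inside the curve, while the inflexion vertebra is the
    # neutral one next to it
    spacing = float(np.mean(np.diff(s)))
    chord = ydat[0] + (s - s[0]) * (ydat[-1] - ydat[0]) / (s[-1] - s[0])
    dev = np.abs(ydat - chord)
    neutral = dev < max(0.02 * dev.max(), 1.0)
    labels: list[str] = []
    for r in sorted(peaks):
        order = np.argsort(np.abs(s - r))
        lab = None
        for j in order:
            if abs(s[j] - r) > 1.6 * spacing:
                break
            if neutral[j]:
                lab = SPINE_LEVELS[j]
                break
        if lab is None:
            lab = SPINE_LEVELS[int(order[0])]
        if lab not in labels:
            labels.append(lab)
    return labels


def coronal_cobb(model: SpineModel, seg: SegmentDef,
                 lam: float = 0.0) -> tuple[float, str]:
    """Coronal Cobb angle of a segment: angle between the perpendiculars to
    the fitted spine curve at the two end vertebrae.

    Returns (magnitude in degrees, convexity side 'left'|'right'|'none');
    the side is the sign of the apex lateral deviation from the end-to-end
    chord (+y = left)."""
    spline = _coronal_spline(model, lam)
    der = spline.derivative(1)
    out = {}
    for label in (seg.upper, seg.lower):
        zq = model[label].body_center[2]
        slope = float(der(-zq))        # dy/ds = -dy/dz; tangent angle vs vertical
        out[label] = np.arctan(slope)
    angle = float(np.degrees(abs(out[seg.upper] - out[seg.lower])))

    apex_label = seg.apex
    if apex_label is None:
        members = levels_between(seg.upper, seg.lower)
        devs = [_chord_deviation(model, seg, l) for l in members]
        apex_label = members[int(np.argmax(np.abs(devs)))]
    dev = _chord_deviation(model, seg, apex_label)
    if abs(dev) < 1e-9:
        side = "none"
    else:
        side = "left" if dev > 0 else "right"
    return angle, side


def _chord_deviation(model: SpineModel, seg: SegmentDef, label: str) -> float:
    pu = model[seg.upper].body_center
    pl = model[seg.lower].body_center
    pa = model[label].body_center
    t = (pu[2] - pa[2]) / (pu[2] - pl[2])
    chord_y = pu[1] + t * (pl[1] - pu[1])
    return float(pa[1] - chord_y)


def _endplate_sagittal_angle(model: SpineModel, label: str, plate: str) -> float:
    """Angle (rad) of the endplate's anterior direction in the sagittal plane."""
    v = model[label]
    corners = v.sup_endplate_corners if plate == "sup" else v.inf_endplate_corners
    proj = (corners - v.body_center) @ v.frame.x
    order = np.argsort(proj)
    posterior = corners[order[:2]].mean(axis=0)
    anterior = corners[order[2:]].mean(axis=0)
    d = anterior - posterior
    dx, dz = d[0], d[2]
    if np.hypot(dx, dz) < 1e-9:
        raise GeometryError(f"{label}: endplate degenerate in sagittal projection")
    return float(np.arctan2(dz, dx))


def sagittal_cobb(model: SpineModel, seg: SegmentDef) -> float:
    """Sagittal Cobb angle between endplate lines, degrees.

    For the kyphosis segment (upper endplate of ``seg.upper``, lower endplate
    of ``seg.lower``) positive means kyphotic; for the lordosis segment
    positive means lordotic."""
    g_up = _endplate_sagittal_angle(model, seg.upper, "sup")
    g_low = _endplate_sagittal_angle(model, seg.lower, "inf")
    value = np.degrees(g_low - g_up)
    if seg.name == "LL":
        value = -value
    return float(value)


def apical_translation(model: SpineModel, apex: str) -> float:
    """AVT: coronal horizontal distance (cm, signed, + = patient-left)
    between the apex body center and the T1 plumb line."""
    dy = model[apex].body_center[1] - model["T1"].body_center[1]
    return float(dy / 10.0)


def stokes_avr(model: SpineModel, level: str) -> float:
    """Axial rotation (deg) from the transverse-plane pedicle chord.

    Angle, about +z, between the right-to-left pedicle direction projected on
    the transverse plane and the global +y axis."""
    v = model[level]
    chord = v.left_pedicle - v.right_pedicle
    vx, vy = chord[0], chord[1]
    if np.hypot(vx, vy) < 1e-9:
        raise GeometryError(f"{level}: pedicle chord projects to a point")
    return float(np.degrees(np.arctan2(-vx, vy)))


def pmc_orientation(model: SpineModel, seg: SegmentDef) -> float:
    """Orientation of the plane of maximum curvature, degrees in [0, 90].

    Angle between the plane through the segment's upper-end, apical and
    lower-end body centers and the sagittal (x-z) plane."""
    if seg.apex is None:
        raise ValidationError(f"{seg.name}: segment has no apex")
    pu = model[seg.upper].body_center
    pa = model[seg.apex].body_center
    pl = model[seg.lower].body_center
    n = np.cross(pa - pu, pl - pu)
    nn = np.linalg.norm(n)
    scale = max(np.linalg.norm(pl - pu), 1.0)
    if nn < 1e-6 * scale**2:
        raise GeometryError(f"{seg.name}: end and apical vertebrae are collinear")
    cosang = abs(n[1]) / nn
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def unfused_count(config=None) -> int:
    """F: number of unfused vertebrae among T1..L5 (17 minus fused levels).

    ``config`` may be None (no instrumentation, F = 17), a (UIV, LIV) label
    pair, or any object exposing ``uiv``/``liv`` attributes."""
    if config is None:
        return 17
    if isinstance(config, (tuple, list)):
        uiv, liv = config
    else:
        uiv, liv = config.uiv, config.liv
    iu, il = level_index(uiv), level_index(liv)
    if iu >= len(SPINE_LEVELS) or il >= len(SPINE_LEVELS):
        raise ValidationError("UIV/LIV must lie within T1..L5")
    if iu >= il:
        raise ValidationError(f"UIV {uiv} must be above LIV {liv}")
    return 17 - (il - iu + 1)


def compute_all(model: SpineModel, segments: dict[str, SegmentDef] | None = None,
                config=None, lam: float = 0.0) -> DescriptorSet:
    """All 12 descriptors plus F, for a given segment definition set.

    A degenerate (collinear) PMC segment — e.g. on a straight spine — is
    reported as 0 deg rather than an error.  Deterministic."""
    segs = default_segments() if segments is None else segments
    coronal = {}
    for name in ("PT", "MT", "TL/L"):
        angle, _side = coronal_cobb(model, segs[name], lam=lam)
        coronal[name] = angle
    avr = {name: stokes_avr(model, segs[name].apex) for name in ("PT", "MT", "TL/L")}
    pmc = {}
    for name in ("PT", "MT", "TL/L"):
        try:
            pmc[name] = pmc_orientation(model, segs[name])
        except GeometryError:
            pmc[name] = 0.0
    return DescriptorSet(
        theta_PT=coronal["PT"],
        theta_MT=coronal["MT"],
        theta_TLL=coronal["TL/L"],
        X_AVT=apical_translation(model, segs["MT"].apex),
        theta_TK=sagittal_cobb(model, segs["TK"]),
        theta_LL=sagittal_cobb(model, segs["LL"]),
        theta_AVR_PT=avr["PT"],
        theta_AVR_MT=avr["MT"],
        theta_AVR_TLL=avr["TL/L"],
        theta_PMC_PT=pmc["PT"],
        theta_PMC_MT=pmc["MT"],
        theta_PMC_TLL=pmc["TL/L"],
        F=unfused_count(config),
    )
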