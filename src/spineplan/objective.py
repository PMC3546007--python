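"""The corrective objective function Ф, surgeon weight profiles, and the
normalization context.

Ф scores a (predicted or simulated) postoperative deformity against the
preoperative state as a weighted sum of squared dimensionless ratios:

    Ф = W1 [a1 (θPT/θPT⁰)² + a2 (θMT/θMT⁰)² + a3 (θTL/L/θTL/L⁰)²
            + a4 (X_AVT/X_AVT⁰)²]
      + W2 [b1 ((θTK−θTKⁿ)/(θTK⁰−θTKⁿ))² + b2 ((θLL−θLLⁿ)/(θLL⁰−θLLⁿ))²]
      + W3 [c1..c3 on the three AVR ratios + c4..c6 on the three PMC ratios]
      + W4 (F⁰/F)²

with all weights stored as percentages (matching how surgeons specify them)
and normalized to fractions inside the evaluation, so Ф at the preoperative
state with F = F⁰ is exactly 1.  θ⁰ are the preoperative values, floored at
5 deg (0.5 cm for AVT) to avoid small denominators; θⁿ are chosen normal
sagittal values, required to differ from the preoperative angles by more
than 5 deg.  F is the unfused-vertebra count; F⁰ the maximum F over the
strategy space, so the mobility term rewards shorter fusions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .descriptors import DescriptorSet
from .spine_geometry import SpinePlanError, ValidationError

__all__ = [
    "WeightProfile",
    "ObjectiveContext",
    "ContextError",
    "load_weight_profiles",
    "default_weight_profiles",
    "make_context",
    "phi",
    "phi_breakdown",
]

_DATA_DIR = Path(__file__).parent / "data"

ANGLE_FLOOR_DEG = 5.0
AVT_FLOOR_CM = 0.5
#: default normal sagittal targets (deg), within published normal ranges
DEFAULT_TK_NORMAL = 35.0
DEFAULT_LL_NORMAL = 50.0


class ContextError(SpinePlanError):
    """Invalid objective normalization context."""


_GROUPS = {
    "W": ("W1", "W2", "W3", "W4"),
    "a": ("a1", "a2", "a3", "a4"),
    "b": ("b1", "b2"),
    "c": ("c1", "c2", "c3", "c4", "c5", "c6"),
}


@dataclass(frozen=True)
class WeightProfile:
    """One surgeon's correction-priority weights, in percent.

    W1..W4 weigh the coronal, sagittal, transverse and mobility blocks;
    a1..a4, b1..b2 and c1..c6 weigh the individual descriptors inside the
    coronal, sagittal and transverse blocks.  Each group sums to 100."""

    surgeon_id: str
    W1: float; W2: float; W3: float; W4: float
    a1: float; a2: float; a3: float; a4: float
    b1: float; b2: float
    c1: float; c2: float; c3: float; c4: float; c5: float; c6: float

    def validate(self) -> None:
        for gname, keys in _GROUPS.items():
            vals = [getattr(self, k) for k in keys]
            if any(v < 0 for v in vals):
                raise ValidationError(
                    f"profile {self.surgeon_id}: negative weight in group {gname!r}")
            total = sum(vals)
            if abs(total - 100.0) > 1e-9:
                raise ValidationError(
                    f"profile {self.surgeon_id}: group {gname!r} sums to {total}, not 100")


def load_weight_profiles(path: str | Path | None = None) -> list[WeightProfile]:
    """Read a weight-profile table (surgeons as columns, weights as rows).

    With no path, loads the packaged table of the eleven surgeon profiles
    S1..S11.  Every profile is validated against the group-sum invariants."""
    path = Path(path) if path is not None else _DATA_DIR / "surgeon_weights.csv"
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    if header[0] != "weight":
        raise ValidationError(f"{path.name}: first column must be 'weight'")
    surgeons = header[1:]
    table: dict[str, dict[str, float]] = {s: {} for s in surgeons}
    for row in rows[1:]:
        if not row:
            continue
        wname = row[0]
        for s, val in zip(surgeons, row[1:]):
            table[s][wname] = float(val)
    profiles = []
    for s in surgeons:
        prof = WeightProfile(surgeon_id=s, **table[s])
        prof.validate()
        profiles.append(prof)
    return profiles


def default_weight_profiles() -> dict[str, WeightProfile]:
    return {p.surgeon_id: p for p in load_weight_profiles()}


@dataclass
class ObjectiveContext:
    """Preoperative normalization for Ф: floored θ⁰ values, normal sagittal
    targets θⁿ, and the maximum unfused count F⁰."""

    preop: DescriptorSet
    theta_TK_n: float
    theta_LL_n: float
    F0: int

    def validate(self) -> None:
        for name in DescriptorSet._ANGULAR:
            if abs(getattr(self.preop, name)) < ANGLE_FLOOR_DEG - 1e-12:
                raise ContextError(f"preop {name} below the 5 deg floor")
        if abs(self.preop.X_AVT) < AVT_FLOOR_CM - 1e-12:
            raise ContextError("preop X_AVT below the 0.5 cm floor")
        if abs(self.theta_TK_n - self.preop.theta_TK) <= ANGLE_FLOOR_DEG:
            raise ContextError("normal TK within 5 deg of the preoperative value")
        if abs(self.theta_LL_n - self.preop.theta_LL) <= ANGLE_FLOOR_DEG:
            raise ContextError("normal LL within 5 deg of the preoperative value")
        if not 0 < self.F0 <= 17:
            raise ContextError(f"F0={self.F0} outside (0, 17]")


def make_context(preop_raw: DescriptorSet, tk_normal: float = DEFAULT_TK_NORMAL,
                 ll_normal: float = DEFAULT_LL_NORMAL, F0: int = 17,
                 angle_floor: float = ANGLE_FLOOR_DEG,
                 avt_floor: float = AVT_FLOOR_CM) -> ObjectiveContext:
    """Build the normalization context from raw preoperative descriptors.

    Angular values below the floor (default 5 deg) are replaced by the floor,
    preserving sign; |AVT| below 0.5 cm is floored analogously.  Normal
    sagittal targets within 5 deg of the preoperative values are rejected."""
    floored = {}
    for name in DescriptorSet._ANGULAR:
        v = getattr(preop_raw, name)
        if abs(v) < angle_floor:
            v = angle_floor if v >= 0 else -angle_floor
        floored[name] = v
    v = preop_raw.X_AVT
    if abs(v) < avt_floor:
        v = avt_floor if v >= 0 else -avt_floor
    floored["X_AVT"] = v
    preop = replace(preop_raw, **floored)
    ctx = ObjectiveContext(preop=preop, theta_TK_n=float(tk_normal),
                           theta_LL_n=float(ll_normal), F0=int(F0))
    ctx.validate()
    return ctx


def phi_breakdown(d: DescriptorSet, ctx: ObjectiveContext, w: WeightProfile,
                  transverse_pairing: str = "table") -> dict[str, float]:
    """Per-term contributions to Ф (same normalization as :func:`phi`).

    ``transverse_pairing`` selects how c1..c6 map onto the six transverse
    descriptors: ``"table"`` (default) pairs c1..c3 with the AVR terms and
    c4..c6 with the PMC terms, matching the published weight table;
    ``"equation"`` swaps the two triples."""
    ctx.validate()
    w.validate()
    if d.F == 0:
        raise ValidationError("F = 0: fully fused spine has no mobility ratio")
    p = ctx.preop

    def ratio(value: float, ref: float) -> float:
        return (value / ref) ** 2

    coronal = (
        w.a1 / 100.0 * ratio(d.theta_PT, p.theta_PT)
        + w.a2 / 100.0 * ratio(d.theta_MT, p.theta_MT)
        + w.a3 / 100.0 * ratio(d.theta_TLL, p.theta_TLL)
        + w.a4 / 100.0 * ratio(d.X_AVT, p.X_AVT)
    )
    sagittal = (
        w.b1 / 100.0 * ratio(d.theta_TK - ctx.theta_TK_n, p.theta_TK - ctx.theta_TK_n)
        + w.b2 / 100.0 * ratio(d.theta_LL - ctx.theta_LL_n, p.theta_LL - ctx.theta_LL_n)
    )
    avr = (ratio(d.theta_AVR_PT, p.theta_AVR_PT),
           ratio(d.theta_AVR_MT, p.theta_AVR_MT),
           ratio(d.theta_AVR_TLL, p.theta_AVR_TLL))
    pmc = (ratio(d.theta_PMC_PT, p.theta_PMC_PT),
           ratio(d.theta_PMC_MT, p.theta_PMC_MT),
           ratio(d.theta_PMC_TLL, p.theta_PMC_TLL))
    if transverse_pairing == "table":
        first, second = avr, pmc
    elif transverse_pairing == "equation":
        first, second = pmc, avr
    else:
        raise ValidationError(f"unknown transverse_pairing {transverse_pairing!r}")
    transverse = (
        w.c1 / 100.0 * first[0] + w.c2 / 100.0 * first[1] + w.c3 / 100.0 * first[2]
        + w.c4 / 100.0 * second[0] + w.c5 / 100.0 * second[1] + w.c6 / 100.0 * second[2]
    )
    mobility = (ctx.F0 / d.F) ** 2
    return {
        "coronal": w.W1 / 100.0 * coronal,
        "sagittal": w.W2 / 100.0 * sagittal,
        "transverse": w.W3 / 100.0 * transverse,
        "mobility": w.W4 / 100.0 * mobility,
    }


def phi(d: DescriptorSet, ctx: ObjectiveContext, w: WeightProfile,
        transverse_pairing: str = "table") -> float:
    """The corrective objective Ф (non-negative scalar; 1 at the
    preoperative state with F = F⁰)."""
    return float(sum(phi_breakdown(d, ctx, w, transverse_pairing).values()))
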