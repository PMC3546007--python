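"""3D spine landmark geometry: data model, coordinate conventions, file I/O.

Conventions
-----------
Global frame: origin at the pelvis body center, +z cephalad, +x anterior,
+y patient-left.  Coronal plane = y-z, sagittal plane = x-z, transverse
plane = x-y.  All coordinates are millimetres.  Under this sign convention a
patient-right coronal convexity has its apex at body_center.y < 0.

Each vertebra carries: body center, superior/inferior endplate centers and
their four corner points, and the two pedicle extremities.  A local
orthonormal frame is derived from the landmarks: local z runs from the
inferior to the superior endplate center, local y along the right-to-left
pedicle direction (orthogonalized against z), and local x = y x z completes
a right-handed triad (x anterior, y patient-left, z cephalad).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LEVELS",
    "SPINE_LEVELS",
    "Frame",
    "VertebraGeom",
    "SpineModel",
    "SpinePlanError",
    "ParseError",
    "GeometryError",
    "ValidationError",
    "level_index",
    "levels_between",
    "vertebra_frame",
    "load_spine",
    "save_spine",
]

#: Anatomical order of the modeled column, cephalad to caudal.
SPINE_LEVELS: tuple[str, ...] = (
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
)
LEVELS: tuple[str, ...] = SPINE_LEVELS + ("PELVIS",)

_LEVEL_INDEX = {lab: i for i, lab in enumerate(LEVELS)}

#: Landmark column names of the CSV dialect, in canonical order.
LANDMARK_NAMES: tuple[str, ...] = (
    "body_center",
    "sup_center", "inf_center",
    "sup_c1", "sup_c2", "sup_c3", "sup_c4",
    "inf_c1", "inf_c2", "inf_c3", "inf_c4",
    "ped_L", "ped_R",
)


class SpinePlanError(Exception):
    """Base class for all spineplan errors."""


class ParseError(SpinePlanError):
    """A landmark or configuration file could not be parsed."""


class GeometryError(SpinePlanError):
    """Degenerate or invalid geometry."""


class ValidationError(SpinePlanError):
    """A domain object violates its invariants."""


def level_index(label: str) -> int:
    """Position of a vertebra label in the anatomical order T1..L5, PELVIS."""
    try:
        return _LEVEL_INDEX[label]
    except KeyError:
        raise ValidationError(f"unknown vertebra label {label!r}") from None


def levels_between(upper: str, lower: str) -> list[str]:
    """Inclusive cephalocaudal list of labels between two levels."""
    iu, il = level_index(upper), level_index(lower)
    if iu > il:
        raise ValidationError(f"{upper} is not above {lower}")
    return list(LEVELS[iu : il + 1])


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """Local orthonormal frame: origin (mm) and axes as a 3x3 matrix whose
    columns are the local x (anterior), y (left) and z (cephalad) unit
    vectors expressed in global coordinates."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)

    def validate(self, tol: float = 1e-9) -> None:
        if self.origin.shape != (3,) or self.axes.shape != (3, 3):
            raise ValidationError("frame has wrong shape")
        err = np.abs(self.axes.T @ self.axes - np.eye(3)).max()
        if err > tol:
            raise ValidationError(f"frame axes not orthonormal (err={err:.2e})")
        if np.linalg.det(self.axes) < 0:
            raise ValidationError("frame is left-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[:, 2]


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError(f"degenerate geometry: {what}")
    return v / n


def vertebra_frame(v: "VertebraGeom") -> Frame:
    """Local frame from landmarks: z along inferior-to-superior endplate
    centers, y along the right-to-left pedicle chord orthogonalized against
    z (Gram-Schmidt), x = y x z; origin at the body center."""
    z = _unit(v.sup_endplate_center - v.inf_endplate_center,
              f"{v.label}: coincident endplate centers")
    yraw = v.left_pedicle - v.right_pedicle
    y = yraw - (yraw @ z) * z
    y = _unit(y, f"{v.label}: pedicle chord parallel to endplate axis")
    x = np.cross(y, z)
    return Frame(origin=np.asarray(v.body_center, dtype=float),
                 axes=np.column_stack([x, y, z]))


# ---------------------------------------------------------------------------
# Vertebra and spine containers
# ---------------------------------------------------------------------------

@dataclass
class VertebraGeom:
    """One vertebra's landmark set (all coordinates mm, global frame)."""

    label: str
    body_center: np.ndarray
    sup_endplate_center: np.ndarray
    inf_endplate_center: np.ndarray
    sup_endplate_corners: np.ndarray  # (4, 3)
    inf_endplate_corners: np.ndarray  # (4, 3)
    left_pedicle: np.ndarray
    right_pedicle: np.ndarray
    frame: Frame | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("body_center", "sup_endplate_center", "inf_endplate_center",
                     "left_pedicle", "right_pedicle"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.sup_endplate_corners = np.asarray(self.sup_endplate_corners, dtype=float)
        self.inf_endplate_corners = np.asarray(self.inf_endplate_corners, dtype=float)
        if self.frame is None:
            self.frame = vertebra_frame(self)

    def validate(self) -> None:
        if self.label not in _LEVEL_INDEX:
            raise ValidationError(f"unknown vertebra label {self.label!r}")
        for p in self.points():
            if not np.all(np.isfinite(p)):
                raise ValidationError(f"{self.label}: non-finite landmark coordinate")
        if not self.sup_endplate_center[2] > self.inf_endplate_center[2]:
            raise ValidationError(
                f"{self.label}: superior endplate not above inferior endplate")
        if self.sup_endplate_corners.shape != (4, 3) or self.inf_endplate_corners.shape != (4, 3):
            raise ValidationError(f"{self.label}: endplate corners must be 4 points each")
        self.frame.validate()
        # pedicles sit posterior to the body center in the local frame
        for ped, side in ((self.left_pedicle, "left"), (self.right_pedicle, "right")):
            local_x = (ped - self.body_center) @ self.frame.x
            if local_x >= 0:
                raise ValidationError(
                    f"{self.label}: {side} pedicle is not posterior to the body center")

    def points(self) -> np.ndarray:
        """All 13 landmarks as a (13, 3) array in canonical order."""
        return np.vstack([
            self.body_center,
            self.sup_endplate_center, self.inf_endplate_center,
            self.sup_endplate_corners, self.inf_endplate_corners,
            self.left_pedicle, self.right_pedicle,
        ])

    @classmethod
    def from_points(cls, label: str, pts: np.ndarray) -> "VertebraGeom":
        pts = np.asarray(pts, dtype=float)
        if pts.shape != (13, 3):
            raise ValidationError(f"{label}: expected 13 landmarks, got {pts.shape}")
        return cls(
            label=label,
            body_center=pts[0],
            sup_endplate_center=pts[1],
            inf_endplate_center=pts[2],
            sup_endplate_corners=pts[3:7],
            inf_endplate_corners=pts[7:11],
            left_pedicle=pts[11],
            right_pedicle=pts[12],
        )

    def transformed(self, R: np.ndarray, t: np.ndarray,
                    about: np.ndarray | None = None) -> "VertebraGeom":
        """Rigidly move the vertebra: p -> about + R (p - about) + t."""
        c = self.body_center if about is None else np.asarray(about, dtype=float)
        pts = (self.points() - c) @ R.T + c + np.asarray(t, dtype=float)
        return VertebraGeom.from_points(self.label, pts)


@dataclass
class SpineModel:
    """Ordered landmark geometry for T1..L5 plus the pelvis (18 records)."""

    vertebrae: list[VertebraGeom]

    def __post_init__(self) -> None:
        self._index = {v.label: i for i, v in enumerate(self.vertebrae)}

    def validate(self) -> None:
        labels = [v.label for v in self.vertebrae]
        if labels != list(LEVELS):
            missing = [l for l in LEVELS if l not in labels]
            extra = [l for l in labels if l not in LEVELS]
            dupes = [l for l in set(labels) if labels.count(l) > 1]
            raise ValidationError(
                "spine must contain exactly the 18 records T1..L5,PELVIS in order"
                + (f"; missing {missing}" if missing else "")
                + (f"; unknown {extra}" if extra else "")
                + (f"; duplicate {dupes}" if dupes else ""))
        for v in self.vertebrae:
            v.validate()
        z = self.body_centers()[:, 2]
        if not np.all(np.diff(z) < 0):
            bad = LEVELS[int(np.argmax(np.diff(z) >= 0))]
            raise ValidationError(f"body-center z does not decrease below {bad}")
        gaps = np.linalg.norm(np.diff(self.body_centers(), axis=0), axis=1)
        if np.any(gaps < 10.0) or np.any(gaps > 60.0):
            raise ValidationError("consecutive body-center spacing outside [10, 60] mm")

    def __getitem__(self, label: str) -> VertebraGeom:
        try:
            return self.vertebrae[self._index[label]]
        except KeyError:
            raise ValidationError(f"spine has no vertebra {label!r}") from None

    def body_centers(self, labels: Sequence[str] | None = None) -> np.ndarray:
        vs = self.vertebrae if labels is None else [self[l] for l in labels]
        return np.vstack([v.body_center for v in vs])

    def copy(self) -> "SpineModel":
        return SpineModel([VertebraGeom.from_points(v.label, v.points().copy())
                           for v in self.vertebrae])


# ---------------------------------------------------------------------------
# File I/O — landmark CSV (label,landmark,x,y,z) and equivalent nested JSON
# ---------------------------------------------------------------------------

def _model_to_records(model: SpineModel) -> Iterable[tuple[str, str, float, float, float]]:
    for v in model.vertebrae:
        for name, p in zip(LANDMARK_NAMES, v.points()):
            yield (v.label, name, float(p[0]), float(p[1]), float(p[2]))


def save_spine(model: SpineModel, path: str | Path) -> None:
    """Write a SpineModel to a landmark file (.csv or .json by extension).

    The model is validated before any bytes are written; coordinates are
    stored at full float precision (repr round-trip)."""
    model.validate()
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "units": "mm",
            "vertebrae": [
                {"label": v.label,
                 "landmarks": {name: [float(c) for c in p]
                               for name, p in zip(LANDMARK_NAMES, v.points())}}
                for v in model.vertebrae
            ],
        }
        text = json.dumps(doc, indent=1)
        path.write_text(text + "\n")
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "landmark", "x", "y", "z"])
        for rec in _model_to_records(model):
            w.writerow([rec[0], rec[1], repr(rec[2]), repr(rec[3]), repr(rec[4])])


def _assemble(per_vertebra: dict[str, dict[str, np.ndarray]], source: str) -> SpineModel:
    vertebrae = []
    for label in LEVELS:
        if label not in per_vertebra:
            raise ParseError(f"{source}: missing vertebra record {label!r}")
        lm = per_vertebra[label]
        missing = [n for n in LANDMARK_NAMES if n not in lm]
        if missing:
            raise ParseError(f"{source}: {label} lacks landmarks {missing}")
        pts = np.vstack([lm[n] for n in LANDMARK_NAMES])
        if not np.all(np.isfinite(pts)):
            raise ParseError(f"{source}: non-finite coordinate in record {label!r}")
        vertebrae.append(VertebraGeom.from_points(label, pts))
    extra = set(per_vertebra) - set(LEVELS)
    if extra:
        raise ParseError(f"{source}: unknown vertebra records {sorted(extra)}")
    model = SpineModel(vertebrae)
    try:
        model.validate()
    except ValidationError as exc:
        raise ParseError(f"{source}: {exc}") from exc
    return model


def load_spine(path: str | Path) -> SpineModel:
    """Read a landmark file written by :func:`save_spine` (CSV or JSON)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such landmark file: {path}")
    per_vertebra: dict[str, dict[str, np.ndarray]] = {}
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        for rec in doc.get("vertebrae", []):
            label = rec.get("label")
            seen = per_vertebra.setdefault(label, {})
            if seen and set(rec.get("landmarks", {})) & set(seen):
                raise ParseError(f"{path.name}: duplicate vertebra record {label!r}")
            for name, xyz in rec.get("landmarks", {}).items():
                seen[name] = np.asarray(xyz, dtype=float)
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"label", "landmark", "x", "y", "z"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ParseError(f"{path.name}: header must contain {sorted(required)}")
            for i, row in enumerate(reader, start=2):
                label, name = row["label"], row["landmark"]
                try:
                    p = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
                except ValueError:
                    raise ParseError(
                        f"{path.name}:{i}: non-numeric coordinate in record {label!r}") from None
                lm = per_vertebra.setdefault(label, {})
                if name in lm:
                    raise ParseError(f"{path.name}:{i}: duplicate landmark {name!r} "
                                     f"for record {label!r}")
                lm[name] = p
    return _assemble(per_vertebra, path.name)
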