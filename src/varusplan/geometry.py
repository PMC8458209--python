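"""Coronal alignment measurement from 2D radiograph landmarks.

Coordinate convention: x increases toward the patient's left, y increases
distally (image convention), units are millimetres.  The ``side`` flag of a
:class:`LandmarkSet` resolves medial/lateral so that all reported angles are
side-independent: varus is positive mFTA and a laterally opening joint space
is positive JLCA for either leg.

Angle definitions
-----------------
mFTA
    Signed angle between the femoral mechanical axis (femoral head centre ->
    femoral knee base) and the tibial mechanical axis (tibial knee base ->
    ankle centre), varus-positive.  The ankle centre is the midpoint of the
    medial and lateral talus borders.
mMPTA
    Medial angle between the distally directed tibial mechanical axis and the
    tibial plateau line.
mLDFA
    Lateral angle between the proximally directed femoral mechanical axis and
    the femoral condylar line.
JLCA
    Angle between condylar and plateau lines, positive when they converge
    medially (joint space opens laterally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Literal, Tuple

import numpy as np

Point = Tuple[float, float]

__all__ = [
    "LandmarkSet",
    "KneeAlignment",
    "DegenerateAxisError",
    "measure_alignment",
    "weight_bearing_line_ratio",
]


class DegenerateAxisError(ValueError):
    """Raised when an axis or joint line collapses to a point (or lines are parallel)."""


POINT_FIELDS = (
    "femoral_head_center",
    "greater_trochanter_apex",
    "femoral_condyle_medial",
    "femoral_condyle_lateral",
    "knee_center_femoral",
    "knee_center_tibial",
    "tibial_plateau_medial",
    "tibial_plateau_lateral",
    "talus_medial",
    "talus_lateral",
)


@dataclass(frozen=True)
class LandmarkSet:
    """Named 2D points (mm) digitised on a calibrated full-leg radiograph."""

    femoral_head_center: Point
    greater_trochanter_apex: Point
    femoral_condyle_medial: Point
    femoral_condyle_lateral: Point
    knee_center_femoral: Point
    knee_center_tibial: Point
    tibial_plateau_medial: Point
    tibial_plateau_lateral: Point
    talus_medial: Point
    talus_lateral: Point
    talus_joint_line: Tuple[Point, Point]
    side: Literal["left", "right"]

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for name in POINT_FIELDS:
            p = getattr(self, name)
            if len(p) != 2 or not all(math.isfinite(c) for c in p):
                raise ValueError(f"landmark {name!r} must be a finite 2D point, got {p!r}")
        for pt in self.talus_joint_line:
            if len(pt) != 2 or not all(math.isfinite(c) for c in pt):
                raise ValueError("talus_joint_line points must be finite 2D points")
        for a, b in (
            ("femoral_condyle_medial", "femoral_condyle_lateral"),
            ("tibial_plateau_medial", "tibial_plateau_lateral"),
            ("talus_medial", "talus_lateral"),
        ):
            if _norm(_vec(getattr(self, a), getattr(self, b))) == 0.0:
                raise ValueError(f"{a} and {b} must be distinct points")

    @property
    def medial_sign(self) -> int:
        """+1 if medial is +x (right leg), -1 if medial is -x (left leg)."""
        return 1 if self.side == "right" else -1

    @property
    def ankle_center(self) -> Point:
        am, al = self.talus_medial, self.talus_lateral
        return ((am[0] + al[0]) / 2.0, (am[1] + al[1]) / 2.0)

    def mirrored(self) -> "LandmarkSet":
        """The same leg reflected about x = 0 with the side flag flipped."""

        def flip(p):
            return (-p[0], p[1])

        kwargs = {name: flip(getattr(self, name)) for name in POINT_FIELDS}
        kwargs["talus_joint_line"] = tuple(flip(p) for p in self.talus_joint_line)
        kwargs["side"] = "left" if self.side == "right" else "right"
        return LandmarkSet(**kwargs)


@dataclass(frozen=True)
class KneeAlignment:
    """The five coronal parameters of one leg (decimal degrees / percent).

    ``mFTA`` is varus-positive; ``JLCA`` is positive for a laterally opening
    joint space; ``WBL_ratio`` is the weight-bearing-line crossing as percent
    of the medial-to-lateral plateau width (may leave [0, 100] when the line
    misses the plateau).
    """

    mFTA: float
    mMPTA: float
    mLDFA: float
    JLCA: float
    WBL_ratio: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
        if not 60.0 < self.mMPTA < 120.0:
            raise ValueError(f"mMPTA {self.mMPTA:.1f} outside plausible range (60, 120)")
        if not 60.0 < self.mLDFA < 120.0:
            raise ValueError(f"mLDFA {self.mLDFA:.1f} outside plausible range (60, 120)")
        if not -10.0 < self.JLCA < 15.0:
            raise ValueError(f"JLCA {self.JLCA:.1f} outside plausible range (-10, 15)")
        if not -100.0 <= self.WBL_ratio <= 200.0:
            raise ValueError(f"WBL_ratio {self.WBL_ratio:.1f} outside plausible range")


def _vec(a: Point, b: Point) -> np.ndarray:
    return np.asarray(b, dtype=float) - np.asarray(a, dtype=float)


def _norm(v: np.ndarray) -> float:
    return float(np.hypot(v[0], v[1]))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = _norm(v)
    if n == 0.0:
        raise DegenerateAxisError(f"degenerate (zero-length) {what}")
    return v / n


def _cross(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _signed_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """CCW angle from u to v in the (x, y-down) plane, degrees in (-180, 180]."""
    return math.degrees(math.atan2(_cross(u, v), float(np.dot(u, v))))


def _unsigned_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v)) / (_norm(u) * _norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def measure_alignment(landmarks: LandmarkSet) -> KneeAlignment:
    """Compute mFTA, mMPTA, mLDFA, JLCA and the WBL ratio from landmarks.

    Raises
    ------
    DegenerateAxisError
        If a mechanical axis or joint line has zero length, or the
        weight-bearing line is parallel to the plateau.
    """
    s = landmarks.medial_sign
    femoral_distal = _unit(
        _vec(landmarks.femoral_head_center, landmarks.knee_center_femoral),
        "femoral mechanical axis",
    )
    tibial_distal = _unit(
        _vec(landmarks.knee_center_tibial, landmarks.ankle_center),
        "tibial mechanical axis",
    )
    plateau_medial = _unit(
        _vec(landmarks.tibial_plateau_lateral, landmarks.tibial_plateau_medial),
        "tibial plateau line",
    )
    condylar_medial = _unit(
        _vec(landmarks.femoral_condyle_lateral, landmarks.femoral_condyle_medial),
        "femoral condylar line",
    )

    mfta = -s * _signed_angle_deg(femoral_distal, tibial_distal)
    mmpta = _unsigned_angle_deg(tibial_distal, plateau_medial)
    mldfa = _unsigned_angle_deg(-femoral_distal, -condylar_medial)
    jlca = s * _signed_angle_deg(plateau_medial, condylar_medial)
    wbl = weight_bearing_line_ratio(landmarks)
    return KneeAlignment(mFTA=mfta, mMPTA=mmpta, mLDFA=mldfa, JLCA=jlca, WBL_ratio=wbl)


def weight_bearing_line_ratio(landmarks: LandmarkSet) -> float:
    """Crossing point of the weight-bearing line on the plateau, in percent.

    The weight-bearing line runs from the femoral head centre to the ankle
    centre.  0% is the medial plateau edge, 100% the lateral edge; values
    outside [0, 100] mean the line misses the plateau.
    """
    p0 = np.asarray(landmarks.femoral_head_center, dtype=float)
    d = _unit(_vec(landmarks.femoral_head_center, landmarks.ankle_center), "weight-bearing line")
    q0 = np.asarray(landmarks.tibial_plateau_medial, dtype=float)
    e = _vec(landmarks.tibial_plateau_medial, landmarks.tibial_plateau_lateral)
    denom = _cross(d, e)
    if abs(denom) < 1e-12:
        raise DegenerateAxisError("weight-bearing line is parallel to the tibial plateau line")
    # Solve p0 + t*d = q0 + u*e for the plateau parameter u (0 medial, 1 lateral).
    u = _cross(d, p0 - q0) / denom
    return 100.0 * float(u)
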