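"""Malalignment test, varus severity bins and correction-potential grouping.

The malalignment test locates the bony origin of a coronal deformity from
the two knee-base angles, with the normal range for both mMPTA and mLDFA
taken as the closed interval [85 deg, 90 deg]:

* tibial deformity:            mMPTA < 85 and mLDFA normal
* femoral deformity:           mLDFA > 90 and mMPTA normal
* tibial + femoral deformity:  mMPTA < 85 and mLDFA > 90
* no bony deformity:           both angles normal

Correction potential quantifies how far each knee-base angle may be driven
before hitting its scenario limit: tibial potential is
``mMPTA_upper - mMPTA`` and femoral potential ``mLDFA - mLDFA_lower``, each
floored at zero.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from typing import TYPE_CHECKING

from .geometry import KneeAlignment

if TYPE_CHECKING:  # pragma: no cover - avoids a circular import with the planner
    from .planner import ScenarioLimits

__all__ = [
    "DeformityLocation",
    "Severity",
    "CorrectionPotential",
    "NORMAL_MMPTA_RANGE",
    "NORMAL_MLDFA_RANGE",
    "classify_location",
    "classify_severity",
    "correction_potential",
]

NORMAL_MMPTA_RANGE = (85.0, 90.0)
NORMAL_MLDFA_RANGE = (85.0, 90.0)

#: Inclusion threshold: only legs with at least this much mechanical varus
#: are part of the study population.
MIN_VARUS_DEG = 3.0


class DeformityLocation(enum.Enum):
    TIBIAL = "tibial"
    FEMORAL = "femoral"
    TIBIAL_AND_FEMORAL = "tibial+femoral"
    NO_BONY_DEFORMITY = "none"


class Severity(enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class PotentialCategory(enum.Enum):
    TIBIAL = "tibial"
    FEMORAL = "femoral"
    TIBIAL_AND_FEMORAL = "tibial+femoral"
    NONE = "none"


@dataclass(frozen=True)
class CorrectionPotential:
    """Realizable valgization (degrees) at each site under scenario limits."""

    tibial: float
    femoral: float

    def __post_init__(self) -> None:
        if self.tibial < 0 or self.femoral < 0:
            raise ValueError("potentials must be non-negative")

    @property
    def category(self) -> PotentialCategory:
        if self.tibial > 0 and self.femoral > 0:
            return PotentialCategory.TIBIAL_AND_FEMORAL
        if self.tibial > 0:
            return PotentialCategory.TIBIAL
        if self.femoral > 0:
            return PotentialCategory.FEMORAL
        return PotentialCategory.NONE


def classify_location(alignment: KneeAlignment) -> DeformityLocation:
    """Locate the bony deformity from the knee-base angles."""
    tibial = alignment.mMPTA < NORMAL_MMPTA_RANGE[0]
    femoral = alignment.mLDFA > NORMAL_MLDFA_RANGE[1]
    if tibial and femoral:
        return DeformityLocation.TIBIAL_AND_FEMORAL
    if tibial:
        return DeformityLocation.TIBIAL
    if femoral:
        return DeformityLocation.FEMORAL
    return DeformityLocation.NO_BONY_DEFORMITY


def classify_severity(mFTA_varus: float) -> Severity:
    """Bin continuous varus into mild [3, 6), moderate [6, 9), severe [9, inf)."""
    if mFTA_varus < MIN_VARUS_DEG:
        raise ValueError(
            f"severity is defined only for mFTA >= {MIN_VARUS_DEG:g} deg varus, "
            f"got {mFTA_varus:.2f}"
        )
    if mFTA_varus < 6.0:
        return Severity.MILD
    if mFTA_varus < 9.0:
        return Severity.MODERATE
    return Severity.SEVERE


def correction_potential(
    alignment: KneeAlignment, limits: ScenarioLimits
) -> CorrectionPotential:
    """Degrees of valgization available at each site before hitting the limits."""
    return CorrectionPotential(
        tibial=max(0.0, limits.mMPTA_upper - alignment.mMPTA),
        femoral=max(0.0, alignment.mLDFA - limits.mLDFA_lower),
    )
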