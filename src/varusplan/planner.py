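"""Deterministic osteotomy simulation under joint-line-obliquity limits.

Every leg is valgized to a fixed target mechanical femorotibial angle
(default 2 deg valgus, i.e. ``target_mFTA = -2`` in the varus-positive
convention) while keeping the post-operative knee-base angles inside the
scenario limits: ``mMPTA <= mMPTA_upper`` (90 anatomic / 95 overcorrection)
and ``mLDFA >= mLDFA_lower`` (85).

Wedge model: first-order additive.  A medial open-wedge HTO of w degrees
raises mMPTA by w and reduces varus by w; a lateral closed-wedge DFO of w
degrees lowers mLDFA by w and reduces varus by w.  JLCA and the other
knee-base angle are unchanged.  WBL_ratio is re-derived from the linearized
relation between mFTA and the plateau crossing; the simulation itself plans
purely in angle space.

Planning rule: the primary osteotomy goes to the site of the greatest
deformity (malalignment test); if no bony deformity exists, to the site of
the greater anatomic correction potential.  If the primary site alone cannot
reach the target within its limit, the primary base angle is driven exactly
to the limit and the remainder is corrected at the opposite site
(double-level).  If both sites at their limits still leave residual varus
beyond the target, the leg is uncorrectable and the plan records the best
achievable alignment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .geometry import KneeAlignment

__all__ = [
    "Site",
    "PlanCategory",
    "ScenarioLimits",
    "OsteotomyPlan",
    "ANATOMIC",
    "OVERCORRECTION",
    "apply_tibial_osteotomy",
    "apply_femoral_osteotomy",
    "choose_primary_site",
    "plan_correction",
    "ideal_level_table",
]


class Site(enum.Enum):
    TIBIA = "tibia"
    FEMUR = "femur"


class PlanCategory(enum.Enum):
    TIBIAL = "tibial"
    FEMORAL = "femoral"
    DOUBLE_LEVEL = "double-level"
    UNCORRECTABLE = "uncorrectable"


@dataclass(frozen=True)
class ScenarioLimits:
    """Post-operative bounds and target alignment for one simulation scenario."""

    mMPTA_upper: float = 90.0
    mLDFA_lower: float = 85.0
    target_mFTA: float = -2.0  # varus-positive convention: -2 is 2 deg valgus

    def __post_init__(self) -> None:
        if not self.mLDFA_lower <= 90.0 <= self.mMPTA_upper:
            raise ValueError(
                "require mLDFA_lower <= 90 < mMPTA_upper, got "
                f"mLDFA_lower={self.mLDFA_lower}, mMPTA_upper={self.mMPTA_upper}"
            )


ANATOMIC = ScenarioLimits(mMPTA_upper=90.0, mLDFA_lower=85.0, target_mFTA=-2.0)
OVERCORRECTION = ScenarioLimits(mMPTA_upper=95.0, mLDFA_lower=85.0, target_mFTA=-2.0)

SCENARIOS: Mapping[str, ScenarioLimits] = {
    "anatomic": ANATOMIC,
    "overcorrection": OVERCORRECTION,
}


@dataclass(frozen=True)
class OsteotomyPlan:
    primary_site: Site
    tibial_wedge: float
    femoral_wedge: float
    post_alignment: KneeAlignment
    category: PlanCategory

    def __post_init__(self) -> None:
        if self.tibial_wedge < 0 or self.femoral_wedge < 0:
            raise ValueError("wedges must be non-negative")


def _shift_wbl(alignment: KneeAlignment, new_mfta: float) -> float:
    # Linearized plateau crossing: the figure-case geometry puts the crossing
    # near 50% at neutral and moves it ~4.5 percentage points per degree of
    # mFTA; adequate for reporting, the planner never branches on it.
    shifted = alignment.WBL_ratio - 4.5 * (new_mfta - alignment.mFTA)
    return min(200.0, max(-100.0, shifted))


def apply_tibial_osteotomy(alignment: KneeAlignment, wedge: float) -> KneeAlignment:
    """Medial open-wedge HTO: mMPTA += wedge, varus -= wedge; mLDFA/JLCA frozen."""
    if wedge < 0:
        raise ValueError(f"wedge must be non-negative, got {wedge}")
    new_mfta = alignment.mFTA - wedge
    return replace(
        alignment,
        mMPTA=alignment.mMPTA + wedge,
        mFTA=new_mfta,
        WBL_ratio=_shift_wbl(alignment, new_mfta),
    )


def apply_femoral_osteotomy(alignment: KneeAlignment, wedge: float) -> KneeAlignment:
    """Lateral closed-wedge DFO: mLDFA -= wedge, varus -= wedge; mMPTA/JLCA frozen."""
    if wedge < 0:
        raise ValueError(f"wedge must be non-negative, got {wedge}")
    new_mfta = alignment.mFTA - wedge
    return replace(
        alignment,
        mLDFA=alignment.mLDFA - wedge,
        mFTA=new_mfta,
        WBL_ratio=_shift_wbl(alignment, new_mfta),
    )


def choose_primary_site(alignment: KneeAlignment, limits: ScenarioLimits) -> Site:
    """Primary osteotomy site: greatest deformity, else greatest potential.

    Deformity magnitude is the deviation beyond the normal range (85-90) of
    the respective knee-base angle.  Site selection always uses the anatomic
    bounds (90/85) so it is stable across scenarios; only wedge capacity
    changes with the scenario.  Ties go to the tibia.
    """
    from .classification import DeformityLocation, classify_location

    location = classify_location(alignment)
    if location is DeformityLocation.TIBIAL:
        return Site.TIBIA
    if location is DeformityLocation.FEMORAL:
        return Site.FEMUR
    if location is DeformityLocation.TIBIAL_AND_FEMORAL:
        tibial_excess = 85.0 - alignment.mMPTA
        femoral_excess = alignment.mLDFA - 90.0
        return Site.TIBIA if tibial_excess >= femoral_excess else Site.FEMUR
    tibial_potential = max(0.0, 90.0 - alignment.mMPTA)
    femoral_potential = max(0.0, alignment.mLDFA - 85.0)
    return Site.TIBIA if tibial_potential >= femoral_potential else Site.FEMUR


def plan_correction(alignment: KneeAlignment, limits: ScenarioLimits) -> OsteotomyPlan:
    """Simulate HTO / DFO / double-level correction to the target alignment.

    Raises
    ------
    ValueError
        If the presenting mFTA is already at or beyond the target (no
        valgization required) or below the 3 deg varus inclusion threshold.
    """
    if alignment.mFTA < 3.0:
        raise ValueError(
            f"planning requires mFTA >= 3 deg varus, got {alignment.mFTA:.2f}"
        )
    delta = alignment.mFTA - limits.target_mFTA
    if delta <= 0:
        raise ValueError("target alignment must be more valgus than the presenting mFTA")

    primary = choose_primary_site(alignment, limits)
    tibial_cap = max(0.0, limits.mMPTA_upper - alignment.mMPTA)
    femoral_cap = max(0.0, alignment.mLDFA - limits.mLDFA_lower)
    caps = {Site.TIBIA: tibial_cap, Site.FEMUR: femoral_cap}
    secondary = Site.FEMUR if primary is Site.TIBIA else Site.TIBIA

    if delta <= caps[primary]:
        wedges = {primary: delta, secondary: 0.0}
        category = (
            PlanCategory.TIBIAL if primary is Site.TIBIA else PlanCategory.FEMORAL
        )
    elif delta <= caps[primary] + caps[secondary]:
        wedges = {primary: caps[primary], secondary: delta - caps[primary]}
        category = PlanCategory.DOUBLE_LEVEL
    else:
        # Best achievable: both base angles driven to their limits.
        wedges = {primary: caps[primary], secondary: caps[secondary]}
        category = PlanCategory.UNCORRECTABLE

    post = apply_tibial_osteotomy(alignment, wedges[Site.TIBIA])
    post = apply_femoral_osteotomy(post, wedges[Site.FEMUR])
    return OsteotomyPlan(
        primary_site=primary,
        tibial_wedge=wedges[Site.TIBIA],
        femoral_wedge=wedges[Site.FEMUR],
        post_alignment=post,
        category=category,
    )


def ideal_level_table(
    cohort: Iterable[KneeAlignment], limits: ScenarioLimits
) -> pd.DataFrame:
    """Severity x plan-category cross-tabulation of counts for a cohort."""
    from .classification import Severity, classify_severity

    severities = [s.value for s in Severity]
    categories = [c.value for c in PlanCategory]
    table = pd.DataFrame(0, index=severities, columns=categories, dtype=int)
    for knee in cohort:
        sev = classify_severity(knee.mFTA).value
        cat = plan_correction(knee, limits).category.value
        table.loc[sev, cat] += 1
    table.index.name = "severity"
    table.columns.name = "category"
    return table
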