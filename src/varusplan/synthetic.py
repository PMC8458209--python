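"""Synthetic varus cohorts and landmark sets with prescribed alignment.

Cohort generation draws mMPTA, mLDFA and JLCA independently from truncated
normal distributions, derives mFTA through the first-order coronal model

    mFTA = (90 - mMPTA) + (mLDFA - 90) + JLCA

and keeps only legs with mFTA at or above the varus inclusion threshold
(rejection sampling).  The induced dependence between the angles in the
accepted sample is an emergent selection effect, not a calibrated joint
distribution, so cohort-level prevalence percentages are not replications of
any particular real cohort.

``inverse_construct_landmarks`` builds a geometrically exact landmark set
that measures back to requested (mFTA, mMPTA, mLDFA); JLCA follows from the
construction as mFTA + mMPTA - mLDFA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Tuple

import numpy as np
from scipy import stats

from .geometry import KneeAlignment, LandmarkSet

__all__ = [
    "SyntheticCohortConfig",
    "generate_cohort",
    "selected_truncated_means",
    "inverse_construct_landmarks",
    "additive_mfta",
]

Bounds = Tuple[float, float]


def additive_mfta(mMPTA: float, mLDFA: float, JLCA: float) -> float:
    """First-order coronal model: varus contributions of tibia, femur and joint."""
    return (90.0 - mMPTA) + (mLDFA - 90.0) + JLCA


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Marginal distributions, truncation bounds and inclusion rule."""

    n: int
    mMPTA_mean: float = 86.0
    mMPTA_sd: float = 2.0
    mLDFA_mean: float = 89.0
    mLDFA_sd: float = 2.0
    JLCA_mean: float = 2.0
    JLCA_sd: float = 2.0
    mMPTA_bounds: Bounds = (78.0, 93.0)
    mLDFA_bounds: Bounds = (83.0, 95.0)
    JLCA_bounds: Bounds = (0.0, 8.0)
    inclusion_min_varus: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for sd in (self.mMPTA_sd, self.mLDFA_sd, self.JLCA_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be positive")
        for lo, hi in (self.mMPTA_bounds, self.mLDFA_bounds, self.JLCA_bounds):
            if not lo < hi:
                raise ValueError("bounds must be ordered (lo < hi)")


def _truncnorm(mean: float, sd: float, bounds: Bounds) -> stats.rv_continuous:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


MAX_ATTEMPT_BATCHES = 1000


def generate_cohort(config: SyntheticCohortConfig) -> List[KneeAlignment]:
    """Sample a cohort of included (mFTA >= threshold) varus legs.

    Deterministic for a fixed config (the seed is part of the config).

    Raises
    ------
    RuntimeError
        If the inclusion rule accepts essentially no draws (infeasible
        config) after a bounded number of batches.
    """
    rng = np.random.default_rng(config.seed)
    dists = {
        "mMPTA": _truncnorm(config.mMPTA_mean, config.mMPTA_sd, config.mMPTA_bounds),
        "mLDFA": _truncnorm(config.mLDFA_mean, config.mLDFA_sd, config.mLDFA_bounds),
        "JLCA": _truncnorm(config.JLCA_mean, config.JLCA_sd, config.JLCA_bounds),
    }
    cohort: List[KneeAlignment] = []
    batch = max(128, config.n)
    for _ in range(MAX_ATTEMPT_BATCHES):
        if len(cohort) >= config.n:
            break
        mmpta = dists["mMPTA"].rvs(size=batch, random_state=rng)
        mldfa = dists["mLDFA"].rvs(size=batch, random_state=rng)
        jlca = dists["JLCA"].rvs(size=batch, random_state=rng)
        mfta = (90.0 - mmpta) + (mldfa - 90.0) + jlca
        keep = mfta >= config.inclusion_min_varus
        for m, t, l, j in zip(
            mfta[keep], mmpta[keep], mldfa[keep], jlca[keep]
        ):
            cohort.append(
                KneeAlignment(
                    mFTA=float(m),
                    mMPTA=float(t),
                    mLDFA=float(l),
                    JLCA=float(j),
                    WBL_ratio=_wbl_from_mfta(float(m)),
                )
            )
            if len(cohort) == config.n:
                break
    if len(cohort) < config.n:
        raise RuntimeError(
            "inclusion rule accepted too few draws; the configuration appears "
            f"infeasible (got {len(cohort)}/{config.n} after "
            f"{MAX_ATTEMPT_BATCHES} batches)"
        )
    return cohort


def _wbl_from_mfta(mfta: float) -> float:
    # Linearized plateau crossing consistent with the planner's model:
    # 50% at neutral, shifting medially ~4.5 percentage points per varus degree.
    return min(200.0, max(-100.0, 50.0 - 4.5 * mfta))


def selected_truncated_means(
    config: SyntheticCohortConfig, grid: int = 2001
) -> dict:
    """Theoretical post-selection means of the three drawn angles (quadrature).

    Computes E[X | mFTA >= threshold] for X in {mMPTA, mLDFA, JLCA} by
    numerical integration over the truncated marginals, using the fact that
    mFTA = J + L - M so the selection probability given X factors through the
    convolution of the other two truncated marginals.
    """
    dm = _truncnorm(config.mMPTA_mean, config.mMPTA_sd, config.mMPTA_bounds)
    dl = _truncnorm(config.mLDFA_mean, config.mLDFA_sd, config.mLDFA_bounds)
    dj = _truncnorm(config.JLCA_mean, config.JLCA_sd, config.JLCA_bounds)
    c = config.inclusion_min_varus

    def axis(dist, bounds):
        x = np.linspace(bounds[0], bounds[1], grid)
        w = dist.pdf(x)
        return x, w

    xm, wm = axis(dm, config.mMPTA_bounds)
    xl, wl = axis(dl, config.mLDFA_bounds)
    xj, wj = axis(dj, config.JLCA_bounds)

    def mean_given_selection(xa, wa, xb, wb, xc_, wc, sign_a, sign_b, sign_c):
        # mFTA = sign_a*A + sign_b*B + sign_c*C + 90 - 90 ... handled by caller
        # via pre-signed axes; here selection is A' + B' + C' >= c with
        # primed = signed contributions.
        A = sign_a * xa
        B = sign_b * xb
        C = sign_c * xc_
        # P(B' + C' >= c - a) per grid point a, by 2D summation.
        BB, CC = np.meshgrid(B, C, indexing="ij")
        WW = np.outer(wb, wc)
        sums = (BB + CC).ravel()
        weights = WW.ravel()
        order = np.argsort(sums)
        sums, weights = sums[order], weights[order]
        cum = np.concatenate([[0.0], np.cumsum(weights)])
        total = cum[-1]
        # tail weight of B'+C' >= t
        idx = np.searchsorted(sums, c - A, side="left")
        tail = total - cum[idx]
        sel = wa * tail
        denom = np.trapezoid(sel, xa)
        num = np.trapezoid(xa * sel, xa)
        return num / denom

    # mFTA = (90 - M) + (L - 90) + J => contribution signs M:-1, L:+1, J:+1
    # (the constants cancel).
    mean_m = mean_given_selection(xm, wm, xl, wl, xj, wj, -1.0, 1.0, 1.0)
    mean_l = mean_given_selection(xl, wl, xm, wm, xj, wj, 1.0, -1.0, 1.0)
    mean_j = mean_given_selection(xj, wj, xm, wm, xl, wl, 1.0, -1.0, 1.0)
    return {"mMPTA": mean_m, "mLDFA": mean_l, "JLCA": mean_j}


def inverse_construct_landmarks(
    alignment_or_mfta,
    mMPTA: float | None = None,
    mLDFA: float | None = None,
    *,
    femur_length: float = 430.0,
    tibia_length: float = 380.0,
    plateau_width: float = 75.0,
    condyle_width: float = 80.0,
    talus_width: float = 55.0,
    knee_gap: float = 8.0,
    side: Literal["left", "right"] = "right",
) -> LandmarkSet:
    """Construct a landmark set that measures back to the requested angles.

    Accepts either a :class:`KneeAlignment` (its mFTA/mMPTA/mLDFA are used)
    or the three angles ``(mFTA, mMPTA, mLDFA)`` positionally.  The tibial
    mechanical axis is laid out vertically with the tibial knee base at the
    origin; all other landmarks follow from the angle conventions.  JLCA is
    emergent: mFTA + mMPTA - mLDFA.
    """
    if isinstance(alignment_or_mfta, KneeAlignment):
        mfta = alignment_or_mfta.mFTA
        mmpta = alignment_or_mfta.mMPTA
        mldfa = alignment_or_mfta.mLDFA
    else:
        if mMPTA is None or mLDFA is None:
            raise TypeError("provide a KneeAlignment or all of (mFTA, mMPTA, mLDFA)")
        mfta, mmpta, mldfa = float(alignment_or_mfta), float(mMPTA), float(mLDFA)

    if not (60.0 < mmpta < 120.0 and 60.0 < mldfa < 120.0 and -30.0 < mfta < 30.0):
        raise ValueError(
            f"non-physiologic request: mFTA={mfta}, mMPTA={mmpta}, mLDFA={mldfa}"
        )
    jlca = mfta + mmpta - mldfa
    if not -10.0 < jlca < 15.0:
        raise ValueError(
            f"requested angles imply a non-physiologic JLCA of {jlca:.2f} deg"
        )

    v = math.radians(mfta)
    theta_t = math.radians(90.0 - mmpta)  # tilt of the plateau's medial direction
    theta_f = math.radians(mfta + 90.0 - mldfa)  # tilt of the condylar medial direction

    def rot(theta: float, x: float, y: float) -> Tuple[float, float]:
        return (
            x * math.cos(theta) - y * math.sin(theta),
            x * math.sin(theta) + y * math.cos(theta),
        )

    kct = (0.0, 0.0)
    ankle = (0.0, tibia_length)
    kcf = (0.0, -knee_gap)
    # femoral axis distal direction for a right leg: (-sin v, cos v)
    head = (kcf[0] + femur_length * math.sin(v), kcf[1] - femur_length * math.cos(v))

    jt_m = rot(theta_t, 1.0, 0.0)  # plateau medial direction (right leg)
    jf_m = rot(theta_f, 1.0, 0.0)  # condylar medial direction (right leg)

    half_w = plateau_width / 2.0
    half_c = condyle_width / 2.0
    half_t = talus_width / 2.0

    lm = {
        "femoral_head_center": head,
        "greater_trochanter_apex": (head[0] - 55.0, head[1] + 15.0),
        "femoral_condyle_medial": (kcf[0] + half_c * jf_m[0], kcf[1] + half_c * jf_m[1]),
        "femoral_condyle_lateral": (kcf[0] - half_c * jf_m[0], kcf[1] - half_c * jf_m[1]),
        "knee_center_femoral": kcf,
        "knee_center_tibial": kct,
        "tibial_plateau_medial": (half_w * jt_m[0], half_w * jt_m[1]),
        "tibial_plateau_lateral": (-half_w * jt_m[0], -half_w * jt_m[1]),
        "talus_medial": (ankle[0] + half_t, ankle[1]),
        "talus_lateral": (ankle[0] - half_t, ankle[1]),
        "talus_joint_line": (
            (ankle[0] + half_t, ankle[1] + 3.0),
            (ankle[0] - half_t, ankle[1] + 3.0),
        ),
    }
    landmarks = LandmarkSet(side="right", **lm)
    if side == "left":
        landmarks = landmarks.mirrored()
    return landmarks
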