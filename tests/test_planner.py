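import numpy as np
import pytest

from varusplan import (
    ANATOMIC,
    OVERCORRECTION,
    PlanCategory,
    ScenarioLimits,
    Site,
    apply_femoral_osteotomy,
    apply_tibial_osteotomy,
    choose_primary_site,
    ideal_level_table,
    plan_correction,
)
from varusplan.synthetic import SyntheticCohortConfig, generate_cohort

from conftest import make_knee, random_knees

CATEGORY_ORDER = {
    PlanCategory.TIBIAL: 0,
    PlanCategory.FEMORAL: 0,
    PlanCategory.DOUBLE_LEVEL: 1,
    PlanCategory.UNCORRECTABLE: 2,
}


def oracle_feasible_wedges(knee, limits, step=0.05):
    """Enumerate (tibial, femoral) wedge pairs reaching the target within limits.

    Independent of the planner: tibial wedges on a `step` grid (plus the exact
    cap endpoint), femoral wedge solved as the remainder and checked against
    its cap.  Returns the list of feasible pairs.
    """
    delta = knee.mFTA - limits.target_mFTA
    cap_t = max(0.0, limits.mMPTA_upper - knee.mMPTA)
    cap_f = max(0.0, knee.mLDFA - limits.mLDFA_lower)
    grid = np.arange(0.0, cap_t + step / 2, step)
    grid = np.unique(np.clip(np.append(grid, [cap_t, delta]), 0.0, cap_t))
    pairs = []
    for t in grid:
        f = delta - t
        if -1e-9 <= f <= cap_f + 1e-9:
            pairs.append((float(t), float(max(0.0, f))))
    return pairs


class TestWedgeOperators:
    def test_tibial_identity(self, fig2_knee):
        assert apply_tibial_osteotomy(fig2_knee, 0.0) == fig2_knee

    def test_tibial_fig2_arithmetic(self):
        knee = make_knee(6.0, 85.3, 89.3, JLCA=2.0)
        out = apply_tibial_osteotomy(knee, 4.7)
        assert out.mMPTA == pytest.approx(90.0)
        assert out.mFTA == pytest.approx(1.3)
        assert out.mLDFA == knee.mLDFA and out.JLCA == knee.JLCA

    def test_tibial_additivity(self, fig3_knee):
        one = apply_tibial_osteotomy(fig3_knee, 3.1)
        two = apply_tibial_osteotomy(one, 2.4)
        direct = apply_tibial_osteotomy(fig3_knee, 5.5)
        assert two.mMPTA == pytest.approx(direct.mMPTA)
        assert two.mFTA == pytest.approx(direct.mFTA)

    def test_femoral_identity(self, fig3_knee):
        assert apply_femoral_osteotomy(fig3_knee, 0.0) == fig3_knee

    def test_femoral_unconstrained_operator(self):
        # The raw operator ignores scenario floors; caps live in plan_correction.
        knee = make_knee(5.5, 88.0, 91.5, JLCA=2.0)
        out = apply_femoral_osteotomy(knee, 7.5)
        assert out.mLDFA == pytest.approx(84.0)
        assert out.mFTA == pytest.approx(-2.0)

    def test_femoral_floor_boundary(self):
        knee = make_knee(6.0, 86.0, 90.0, JLCA=2.0)
        out = apply_femoral_osteotomy(knee, 5.0)
        assert out.mLDFA == pytest.approx(85.0)

    @pytest.mark.parametrize("op", [apply_tibial_osteotomy, apply_femoral_osteotomy])
    def test_negative_wedge_rejected(self, op, fig2_knee):
        with pytest.raises(ValueError, match="non-negative"):
            op(fig2_knee, -0.1)


class TestPrimarySite:
    def test_tibial_deformity(self, fig3_knee):
        assert choose_primary_site(fig3_knee, ANATOMIC) is Site.TIBIA

    def test_no_deformity_greater_potential(self, fig2_knee):
        # tibial potential 4.7 > femoral 4.3
        assert choose_primary_site(fig2_knee, ANATOMIC) is Site.TIBIA

    def test_combined_deformity_larger_excess_wins(self):
        knee = make_knee(8.0, 84.0, 92.0, JLCA=4.0)  # femoral excess 2 > tibial 1
        assert choose_primary_site(knee, ANATOMIC) is Site.FEMUR

    def test_femoral_deformity(self):
        knee = make_knee(5.5, 88.0, 91.5, JLCA=2.0)
        assert choose_primary_site(knee, ANATOMIC) is Site.FEMUR

    def test_tie_breaks_to_tibia(self):
        knee = make_knee(6.0, 84.0, 91.0, JLCA=2.0)  # both excesses exactly 1
        assert choose_primary_site(knee, ANATOMIC) is Site.TIBIA

    def test_scenario_stable_site_choice(self, rng):
        for knee in random_knees(rng, 300):
            assert choose_primary_site(knee, ANATOMIC) is choose_primary_site(
                knee, OVERCORRECTION
            )


class TestPlanCorrection:
    def test_tibial_deformity_can_still_need_double_level(self):
        knee = make_knee(5.0, 84.0, 89.0, JLCA=0.0)
        plan = plan_correction(knee, ANATOMIC)
        assert plan.category is PlanCategory.DOUBLE_LEVEL
        assert plan.tibial_wedge == pytest.approx(6.0)
        assert plan.femoral_wedge == pytest.approx(1.0)
        assert plan.post_alignment.mMPTA == pytest.approx(90.0)

    def test_fig2_overcorrection_isolated_hto(self, fig2_knee):
        plan = plan_correction(fig2_knee, OVERCORRECTION)
        assert plan.category is PlanCategory.TIBIAL
        assert plan.primary_site is Site.TIBIA
        assert plan.tibial_wedge == pytest.approx(8.0)
        assert plan.femoral_wedge == 0.0
        assert plan.post_alignment.mMPTA == pytest.approx(93.3)
        assert plan.post_alignment.mFTA == pytest.approx(-2.0)

    def test_fig2_anatomic_double_level(self, fig2_knee):
        plan = plan_correction(fig2_knee, ANATOMIC)
        assert plan.category is PlanCategory.DOUBLE_LEVEL
        assert plan.tibial_wedge == pytest.approx(4.7)
        assert plan.femoral_wedge == pytest.approx(3.3)
        assert plan.post_alignment.mFTA == pytest.approx(-2.0)

    def test_fig3_anatomic_uncorrectable(self, fig3_knee):
        plan = plan_correction(fig3_knee, ANATOMIC)
        assert plan.category is PlanCategory.UNCORRECTABLE
        # best achievable: both base angles at their limits
        assert plan.post_alignment.mMPTA == pytest.approx(90.0)
        assert plan.post_alignment.mLDFA == pytest.approx(85.0)
        assert plan.post_alignment.mFTA == pytest.approx(10.0 - 5.6 - 5.0)

    def test_fig3_overcorrection_double_level(self, fig3_knee):
        plan = plan_correction(fig3_knee, OVERCORRECTION)
        assert plan.category is PlanCategory.DOUBLE_LEVEL
        assert plan.tibial_wedge == pytest.approx(10.6)
        assert plan.femoral_wedge == pytest.approx(1.4)
        assert plan.post_alignment.mFTA == pytest.approx(-2.0)

    def test_below_inclusion_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            plan_correction(make_knee(2.0, 86.0, 89.0, JLCA=-1.0), ANATOMIC)

    def test_no_valgization_needed_rejected(self, fig2_knee):
        limits = ScenarioLimits(mMPTA_upper=95.0, target_mFTA=7.0)
        with pytest.raises(ValueError, match="target"):
            plan_correction(fig2_knee, limits)

    @pytest.mark.parametrize("limits", [ANATOMIC, OVERCORRECTION])
    def test_feasibility_oracle_agreement(self, rng, limits):
        for knee in random_knees(rng, 2000):
            plan = plan_correction(knee, limits)
            pairs = oracle_feasible_wedges(knee, limits)
            if plan.category is PlanCategory.UNCORRECTABLE:
                assert not pairs
            else:
                assert pairs
                # single-site plans are exactly those the oracle can realize
                # with the whole correction at the planner's primary site
                single = any(
                    (t == 0.0) if plan.primary_site is Site.FEMUR else (f == 0.0)
                    for t, f in pairs
                )
                if plan.category in (PlanCategory.TIBIAL, PlanCategory.FEMORAL):
                    assert single
                else:
                    assert not single

    def test_anatomic_minimal_site_count(self, rng):
        # Under anatomic limits the primary site always carries the larger
        # capacity, so the planner's category equals the oracle's minimal
        # site count with no primary-site qualification.
        for knee in random_knees(rng, 1000):
            plan = plan_correction(knee, ANATOMIC)
            pairs = oracle_feasible_wedges(knee, ANATOMIC)
            any_single = any(t == 0.0 or f == 0.0 for t, f in pairs)
            if plan.category in (PlanCategory.TIBIAL, PlanCategory.FEMORAL):
                assert any_single
            elif plan.category is PlanCategory.DOUBLE_LEVEL:
                assert pairs and not any_single

    @pytest.mark.parametrize("limits", [ANATOMIC, OVERCORRECTION])
    def test_conservation_and_limit_compliance(self, rng, limits):
        for knee in random_knees(rng, 1000):
            plan = plan_correction(knee, limits)
            post = plan.post_alignment
            if plan.category is not PlanCategory.UNCORRECTABLE:
                delta = knee.mFTA - limits.target_mFTA
                assert plan.tibial_wedge + plan.femoral_wedge == pytest.approx(delta)
                assert post.mFTA == pytest.approx(limits.target_mFTA)
                # limits bound the correction; a knee may present outside them
                assert post.mMPTA <= max(limits.mMPTA_upper, knee.mMPTA) + 1e-9
                assert post.mLDFA >= min(limits.mLDFA_lower, knee.mLDFA) - 1e-9
            assert post.JLCA == knee.JLCA  # frozen during simulation

    def test_single_site_plans_have_zero_other_wedge(self, rng):
        for knee in random_knees(rng, 500):
            plan = plan_correction(knee, OVERCORRECTION)
            if plan.category is PlanCategory.TIBIAL:
                assert plan.femoral_wedge == 0.0
            elif plan.category is PlanCategory.FEMORAL:
                assert plan.tibial_wedge == 0.0

    def test_scenario_monotonicity(self, rng):
        worse = 0
        for knee in random_knees(rng, 2000):
            c90 = plan_correction(knee, ANATOMIC).category
            c95 = plan_correction(knee, OVERCORRECTION).category
            if CATEGORY_ORDER[c95] > CATEGORY_ORDER[c90]:
                worse += 1
        assert worse == 0


class TestIdealLevelTable:
    def test_single_mild_hto_knee(self):
        knee = make_knee(4.0, 84.0, 89.0, JLCA=-1.0)
        table = ideal_level_table([knee], ANATOMIC)
        assert table.loc["mild", "tibial"] == 1
        assert table.to_numpy().sum() == 1

    def test_all_identical_single_cell(self, fig3_knee):
        table = ideal_level_table([fig3_knee] * 7, ANATOMIC)
        assert table.loc["severe", "uncorrectable"] == 7
        assert (table.to_numpy() > 0).sum() == 1

    def test_empty_cohort(self):
        table = ideal_level_table([], ANATOMIC)
        assert table.to_numpy().sum() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cohort_level_monotonicity(self, seed):
        cohort = generate_cohort(SyntheticCohortConfig(n=300, seed=seed))
        t90 = ideal_level_table(cohort, ANATOMIC)
        t95 = ideal_level_table(cohort, OVERCORRECTION)
        assert t95["tibial"].sum() >= t90["tibial"].sum()
        assert t95["uncorrectable"].sum() <= t90["uncorrectable"].sum()
        assert t95["femoral"].sum() == t90["femoral"].sum()  # DFO scenario-stable
        assert t90.to_numpy().sum() == t95.to_numpy().sum() == 300
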