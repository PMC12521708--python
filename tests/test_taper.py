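import math
from collections import Counter
from dataclasses import replace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oeptools import (
    ACUTE_POLICY,
    CHRONIC_POLICY,
    ConsumptionEntry,
    PatientCase,
    TaperPolicy,
    ValidationError,
    apply_grace_period,
    backup_dose,
    baseline_from_24h,
    build_plan,
    generate_taper,
    is_stabilized,
    select_policy,
    tiered_taper,
)
from oeptools.taper import plan_id_for


def make_case(**kw):
    defaults = dict(
        opioid_status="naive",
        pain_type="acute",
        last24h=(ConsumptionEntry("morphine", 40, "fixed"), ConsumptionEntry("morphine", 10, "backup")),
        pain_stable_hours=48.0,
    )
    defaults.update(kw)
    return PatientCase(**defaults)


class TestBaseline:
    def test_fixed_and_backup_both_count(self, fx_formulary):
        assert baseline_from_24h(make_case(), fx_formulary) == 50.0

    def test_mixed_drugs_convert_before_summing(self, fx_formulary):
        case = make_case(
            last24h=(ConsumptionEntry("drug_x", 10, "fixed"), ConsumptionEntry("morphine", 5, "backup"))
        )
        assert baseline_from_24h(case, fx_formulary) == 25.0

    def test_empty_consumption_is_an_error(self, fx_formulary):
        with pytest.raises(ValidationError):
            baseline_from_24h(make_case(last24h=()), fx_formulary)

    def test_naive_patient_cannot_have_prehospital_dose(self):
        with pytest.raises(ValidationError):
            make_case(opioid_status="naive", prehospital_ome=10)


class TestStabilization:
    @pytest.mark.parametrize(
        "stable_h, count, backup_ome, fixed, expected",
        [
            (48, 1, 4, 50, True),  # within all defaults
            (12, 0, 0, 50, False),  # window unmet
            (48, 5, 20, 50, False),  # count and fraction both exceeded
            (48, 2, 5.0, 50, True),  # exactly at the 10% boundary
            (48, 3, 4, 50, False),  # count alone exceeded
        ],
    )
    def test_defaults(self, stable_h, count, backup_ome, fixed, expected):
        case = make_case(pain_stable_hours=stable_h)
        assert is_stabilized(case, count, backup_ome, fixed) is expected

    def test_window_cannot_drop_below_24h(self):
        with pytest.raises(ValidationError):
            is_stabilized(make_case(), 0, 0, 50, window_hours=12)


class TestSelectPolicy:
    def test_acute_naive(self):
        p = select_policy(make_case(), 50)
        assert (p.reduction_fraction, p.step_interval_days, p.grace_days, p.target_ome) == (0.25, 2, 0, 0)

    def test_chronic_user_with_discharge(self):
        case = make_case(
            opioid_status="chronic_user", pain_type="chronic", prehospital_ome=20, discharge_day=1
        )
        p = select_policy(case, 50)
        assert (p.reduction_fraction, p.step_interval_days, p.grace_days, p.target_ome) == (0.10, 3, 2, 20)

    def test_acute_chronic_user_targets_prehospital_dose(self):
        p = select_policy(make_case(opioid_status="chronic_user", prehospital_ome=30), 60)
        assert p.target_ome == 30

    def test_plan_ids_cover_the_four_trajectories(self):
        assert plan_id_for(make_case(pain_type="chronic")) == "plan1"
        assert plan_id_for(make_case(pain_type="chronic", discharge_day=1)) == "plan2"
        assert plan_id_for(make_case(pain_type="acute")) == "plan3"
        assert plan_id_for(make_case(pain_type="acute", discharge_day=1)) == "plan4"


class TestGenerateTaper:
    def test_rapid_preset_from_50(self):
        plan = generate_taper(50, ACUTE_POLICY, "plan3")
        by_day = {s.day: s.fixed_ome for s in plan.steps}
        assert by_day[0] == 50 and by_day[1] == 37.5 and by_day[3] == 25
        assert by_day[5] == 12.5 and by_day[7] == 0
        assert plan.last_day == 7
        assert plan.reduction_days == (1, 3, 5, 7)

    def test_gradual_preset_makes_ten_reductions_ending_day_28(self):
        plan = generate_taper(50, CHRONIC_POLICY, "plan1")
        assert len(plan.reduction_days) == 10
        assert plan.reduction_days[-1] == 1 + 3 * 9 == 28

    def test_nonzero_target_with_exact_division(self):
        policy = replace(ACUTE_POLICY, target_ome=15)
        plan = generate_taper(60, policy)
        assert plan.reduction_days == (1, 3, 5)
        assert plan.steps[-1].fixed_ome == 15
        assert len(plan.reduction_days) == math.ceil((60 - 15) / 15)

    def test_baseline_at_or_below_target_is_an_error(self):
        with pytest.raises(ValidationError, match="[Nn]othing to reduce"):
            generate_taper(10, replace(ACUTE_POLICY, target_ome=10))

    def test_backup_carried_until_target_then_dropped(self):
        plan = generate_taper(50, ACUTE_POLICY)
        for s in plan.steps:
            if s.fixed_ome > 0:
                assert s.backup_ome == pytest.approx(50 / 8)
            else:
                assert s.backup_ome == 0

    @given(
        baseline=st.floats(10, 500, allow_nan=False),
        fraction=st.sampled_from([0.05, 0.10, 0.15, 0.20, 0.25]),
        interval=st.sampled_from([2, 3]),
        target_frac=st.floats(0, 0.9),
    )
    def test_plan_invariants(self, baseline, fraction, interval, target_frac):
        """Non-increasing, lands exactly on target, reduction count = ceil(span/step)."""
        target = baseline * target_frac
        policy = TaperPolicy(
            reduction_fraction=fraction, step_interval_days=interval, target_ome=target
        )
        plan = generate_taper(baseline, policy)
        doses = [s.fixed_ome for s in plan.steps]
        assert all(a >= b - 1e-9 for a, b in zip(doses, doses[1:]))
        assert doses[0] == baseline
        assert doses[-1] == pytest.approx(target)
        assert all(d >= target - 1e-9 for d in doses)
        expected_n = math.ceil((baseline - target) / (fraction * baseline) - 1e-9)
        assert len(plan.reduction_days) == expected_n

    @given(baseline=st.floats(1, 1000, allow_nan=False))
    def test_linear_steps_not_compounding(self, baseline):
        """After 2 reductions the dose is B(1-2f), never B(1-f)^2."""
        for policy in (ACUTE_POLICY, CHRONIC_POLICY):
            f = policy.reduction_fraction
            plan = generate_taper(baseline, policy)
            day2 = policy.first_reduction_day + policy.step_interval_days
            linear = baseline * (1 - 2 * f)
            compound = baseline * (1 - f) ** 2
            assert plan.dose_on(day2) == pytest.approx(linear, rel=1e-12)
            assert abs(plan.dose_on(day2) - compound) > 1e-6 * baseline

    @given(baseline=st.floats(5, 800, allow_nan=False))
    def test_preset_reduction_counts_are_baseline_free(self, baseline):
        assert len(generate_taper(baseline, ACUTE_POLICY).reduction_days) == 4
        assert len(generate_taper(baseline, CHRONIC_POLICY).reduction_days) == 10


class TestGracePeriod:
    def test_discharge_day_1_shifts_later_reductions(self):
        plan = apply_grace_period(generate_taper(50, ACUTE_POLICY), 1, 2)
        by_day = {s.day: s.fixed_ome for s in plan.steps}
        # day-1 dose held through day 4; reductions resume on day 5
        assert all(by_day[d] == 37.5 for d in (1, 2, 3, 4))
        assert by_day[5] == 25 and by_day[7] == 12.5 and by_day[9] == 0

    def test_discharge_after_last_reduction_leaves_plan_unchanged(self):
        plan = generate_taper(50, ACUTE_POLICY)
        assert apply_grace_period(plan, 7, 2) == plan

    def test_nonpositive_grace_rejected(self):
        with pytest.raises(ValidationError):
            apply_grace_period(generate_taper(50, ACUTE_POLICY), 1, 0)

    @given(
        baseline=st.floats(10, 300, allow_nan=False),
        discharge=st.integers(0, 6),
        grace=st.integers(1, 4),
        fraction=st.sampled_from([0.10, 0.25]),
    )
    def test_dose_levels_preserved_and_ordered(self, baseline, discharge, grace, fraction):
        policy = TaperPolicy(reduction_fraction=fraction, step_interval_days=2)
        plan = generate_taper(baseline, policy)
        shifted = apply_grace_period(plan, discharge, grace)
        assert Counter(shifted.dose_levels) == Counter(plan.dose_levels)
        assert shifted.dose_levels == plan.dose_levels  # order preserved too
        delayed = [d for d in plan.reduction_days if d > discharge]
        expect = tuple(
            d + grace if d > discharge else d for d in plan.reduction_days
        )
        assert shifted.reduction_days == expect if delayed else shifted == plan


class TestTieredTaper:
    def test_excess_phase_reaches_maintenance(self):
        plan = tiered_taper(20, 60, ACUTE_POLICY)
        by_day = {s.day: s.fixed_ome for s in plan.steps}
        assert [by_day[d] for d in (0, 1, 3, 5, 7)] == [60, 50, 40, 30, 20]
        assert plan.steps[-1].fixed_ome == 20

    def test_phase2_already_at_target_is_degenerate(self):
        plan = tiered_taper(20, 60, ACUTE_POLICY, replace(CHRONIC_POLICY, target_ome=20))
        assert plan.steps[-1].fixed_ome == 20
        assert len(plan.reduction_days) == 4

    def test_phase2_continues_under_chronic_policy(self):
        plan = tiered_taper(20, 60, ACUTE_POLICY, replace(CHRONIC_POLICY, target_ome=0))
        doses = [s.fixed_ome for s in plan.steps]
        assert all(a >= b - 1e-9 for a, b in zip(doses, doses[1:]))
        assert 20 in doses  # continuous at the phase boundary
        assert plan.steps[-1].fixed_ome == 0
        # phase 2 steps remove 10% of the maintenance dose each
        assert len(plan.reduction_days) == 4 + 10

    def test_current_below_maintenance_rejected(self):
        with pytest.raises(ValidationError):
            tiered_taper(60, 20, ACUTE_POLICY)


class TestBackupDose:
    @pytest.mark.parametrize(
        "fraction, expected", [(1 / 10, 5.0), (1 / 6, 50 / 6), (1 / 8, 6.25)]
    )
    def test_within_bracket(self, fraction, expected):
        assert backup_dose(50, fraction) == pytest.approx(expected)

    @pytest.mark.parametrize("fraction", [1 / 4, 1 / 20, 0, -0.1])
    def test_outside_bracket_rejected(self, fraction):
        with pytest.raises(ValidationError):
            backup_dose(50, fraction)


class TestBuildPlan:
    def test_end_to_end_acute_discharge(self, fx_formulary):
        case = make_case(discharge_day=1)
        plan = build_plan(case, fx_formulary)
        assert plan.plan_id == "plan4"
        assert plan.baseline_ome == 50
        assert plan.reduction_days == (1, 5, 7, 9)

    def test_serialization_round_trip(self, fx_formulary):
        from oeptools import TaperPlan
        import json

        plan = build_plan(make_case(), fx_formulary)
        again = TaperPlan.from_dict(json.loads(plan.to_json()))
        assert again == plan
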