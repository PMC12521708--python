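import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oeptools import (
    DelphiDataset,
    FixtureSpec,
    ValidationError,
    brennan_prediger,
    consensus_report,
    default_planted_items,
    icc_a1,
    item_consensus,
    make_delphi_panel,
    percent_agreement,
    round_consensus_rate,
)
from oeptools.consensus import test_retest_stability as retest_stability


class TestItemConsensus:
    def test_unanimous_agreement(self):
        res = item_consensus([7] * 10)
        assert (res.consensus, res.prop_agree, res.mean_rating) == (True, 1.0, 7.0)

    def test_unanimous_disagreement(self):
        res = item_consensus([1] * 10)
        assert (res.consensus, res.prop_agree, res.mean_rating) == (False, 0.0, 1.0)

    def test_boundary_case_exactly_eighty_percent(self):
        res = item_consensus([7, 7, 7, 7, 4])
        assert res.consensus and res.prop_agree == 0.8 and res.mean_rating == pytest.approx(6.4)

    def test_high_proportion_but_low_mean_fails(self):
        # 4/5 at the cut but mean below 4.5: both conditions are required
        res = item_consensus([5, 5, 5, 5, 1], mean_threshold=4.5)
        assert res.prop_agree == 0.8 and res.mean_rating == pytest.approx(4.2)
        assert not res.consensus

    def test_missing_excluded_from_denominator(self):
        res = item_consensus([7, 7, np.nan, np.nan])
        assert res.prop_agree == 1.0 and res.mean_rating == 7.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValidationError):
            item_consensus([np.nan, np.nan])

    @given(st.permutations([7, 6, 5, 4, 3, 2, 1, 5, 6]))
    def test_permutation_invariant(self, ratings):
        assert item_consensus(ratings) == item_consensus(sorted(ratings))


class TestRoundRate:
    def test_planted_panel_recovered_exactly(self):
        spec = FixtureSpec(
            seed=3,
            planted_consensus_items=default_planted_items(43, 49),
            consensus_strength=1.0,
            offplant_strength=0.0,
        )
        rc = round_consensus_rate(make_delphi_panel(spec), 1)
        assert (rc.k_consensus, rc.n_items, rc.percent) == (43, 49, 87.8)
        winners = {item for item, r in rc.per_item.items() if r.consensus}
        assert winners == {f"item{i:02d}" for i in range(43)}

    def test_zero_consensus_panel(self):
        spec = FixtureSpec(seed=1, consensus_strength=0.0, offplant_strength=0.0)
        rc = round_consensus_rate(make_delphi_panel(spec), 1)
        assert rc.k_consensus == 0 and rc.percent == 0.0

    def test_absent_round_rejected(self):
        panel = make_delphi_panel(FixtureSpec(seed=1))
        with pytest.raises(ValidationError):
            round_consensus_rate(panel, 3)


class TestStability:
    def panel(self, perturb=0.0, seed=5):
        return make_delphi_panel(
            FixtureSpec(
                seed=seed,
                planted_consensus_items=default_planted_items(43, 49),
                round2_perturbation=perturb,
            )
        )

    def test_identical_rounds_give_unity_both_methods(self):
        panel = self.panel(perturb=0.0)
        for method in ("pearson", "icc_a1"):
            coef, lo, hi, stable = retest_stability(panel, method)
            assert coef == 1.0 and stable

    def test_perturbed_rounds_below_unity_but_stable(self):
        coef, lo, hi, stable = retest_stability(self.panel(perturb=0.2), "icc_a1")
        assert 0.7 <= coef < 1.0 and lo < coef < hi and stable

    def test_stability_flag_tracks_threshold(self):
        coef, *_, stable = retest_stability(self.panel(perturb=0.2), "icc_a1")
        assert stable == (coef >= 0.70)
        _, _, _, strict = retest_stability(self.panel(perturb=0.2), "icc_a1", stability_threshold=coef + 0.01)
        assert not strict

    def test_pearson_symmetric_in_round_order(self):
        panel = self.panel(perturb=0.3)
        swapped = panel.ratings.copy()
        swapped["round"] = swapped["round"].map({1: 2, 2: 1})
        a = retest_stability(panel, "pearson")[0]
        b = retest_stability(DelphiDataset(swapped), "pearson")[0]
        assert a == pytest.approx(b)

    def test_changed_items_are_excluded(self):
        # corrupt round-2 ratings of changed items only: stability unaffected
        panel = self.panel(perturb=0.1)
        df = panel.ratings.copy()
        mask = df["item_changed"] & (df["round"] == 2)
        df.loc[mask, "rating"] = 1.0
        assert retest_stability(DelphiDataset(df), "icc_a1")[0] == pytest.approx(
            retest_stability(panel, "icc_a1")[0]
        )

    def test_too_few_unchanged_items_rejected(self):
        spec = FixtureSpec(seed=1, n_items=5, planted_consensus_items=frozenset([0, 1, 2]))
        panel = make_delphi_panel(spec)
        df = panel.ratings[panel.ratings["item_id"].isin(["item00", "item01", "item03", "item04"])]
        with pytest.raises(ValidationError, match="unchanged"):
            retest_stability(DelphiDataset(df.copy()), "icc_a1")


class TestIccAgainstReference:
    def test_matches_pingouin_on_random_table(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        data = rng.normal(5, 1, (10, 8)) + rng.normal(0, 0.5, (10, 1))
        coef, lo, hi = icc_a1(data)
        long = pd.DataFrame(
            [
                {"subj": i, "rater": j, "score": data[i, j]}
                for i in range(10)
                for j in range(8)
            ]
        )
        ref = pg.intraclass_corr(long, "subj", "rater", "score")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0] if (ref["Type"] == "ICC(A,1)").any() else ref[ref["Type"] == "ICC2"].iloc[0]
        assert coef == pytest.approx(float(row["ICC"]), abs=1e-9)
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        ref_lo, ref_hi = row[ci_col]
        assert lo == pytest.approx(float(ref_lo), abs=0.01)
        assert hi == pytest.approx(float(ref_hi), abs=0.01)


class TestCoderAgreement:
    def test_percent_agreement_examples(self):
        assert percent_agreement(list("aabc"), list("abbc")) == 0.75
        assert percent_agreement(list("abc"), list("abc")) == 1.0
        assert percent_agreement(list("abc"), list("bca")) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            percent_agreement([1, 2], [1])

    def test_brennan_prediger_closed_form(self):
        # P_o = 0.9, q = 10 -> (0.9 - 0.1)/0.9
        a = list("abcdefghij") * 9 + list("ab" * 5)
        b = list("abcdefghij") * 9 + list("ba" * 5)
        assert percent_agreement(a, b) == pytest.approx(0.9)
        assert brennan_prediger(a, b, 10) == pytest.approx(0.8 / 0.9)

    def test_perfect_and_chance_levels(self):
        assert brennan_prediger(list("abab"), list("abab"), 2) == 1.0
        # P_o = 1/q = 0.5 at q=2 -> exactly chance
        assert brennan_prediger(list("aabb"), list("abab"), 2) == pytest.approx(0.0)

    def test_approaches_raw_agreement_for_many_categories(self):
        a = list(range(100))
        b = list(range(90)) + [999] * 10
        kappa = brennan_prediger(a, b, 1000)
        assert kappa == pytest.approx(percent_agreement(a, b), abs=1e-3)

    def test_q_below_two_rejected(self):
        with pytest.raises(ValidationError):
            brennan_prediger([1], [1], 1)


class TestReport:
    def test_report_shape(self):
        spec = FixtureSpec(seed=2, planted_consensus_items=default_planted_items(10, 20), n_items=20)
        report = consensus_report(make_delphi_panel(spec))
        assert set(report["rounds"]) == {"1", "2"}
        assert set(report["stability"]) == {"pearson", "icc_a1"}
        item = next(iter(report["rounds"]["1"]["items"].values()))
        assert {"consensus", "prop_agree", "mean", "ci95"} <= set(item)
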