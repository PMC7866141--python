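import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermoplace as tp
from thermoplace.stats import (
    CohortError,
    PreferenceCall,
    analyze_cohort,
    call_drug_effect,
    call_preference,
    rm_anova,
    stars,
    tukey_pairwise,
    validate_cohort,
)

TPS = ["before_oxa", "pre_drug", "post_drug"]


def tiny_cohort(values_by_subject: dict, session_id: int = 1) -> pd.DataFrame:
    """Tidy table from {subject: [pct at the three timepoints]}."""
    rows = []
    for subj, vals in values_by_subject.items():
        for tpn, v in zip(TPS, vals):
            rows.append(
                {
                    "subject": subj,
                    "session_id": session_id,
                    "timepoint": tpn,
                    "pct_colder": float(v),
                    "t_cold": 0.0,
                    "t_warm": 5.0,
                }
            )
    return pd.DataFrame(rows)


class TestValidateCohort:
    def test_accepts_simulated_cohort(self):
        coh = tp.simulate_cohort(3, tp.standard_protocol(), seed=0)
        assert validate_cohort(coh) is coh

    def test_empty_table_rejected(self):
        with pytest.raises(CohortError, match="empty|missing"):
            validate_cohort(pd.DataFrame(columns=["subject", "session_id", "timepoint", "pct_colder"]))

    def test_duplicate_cells_rejected(self):
        df = tiny_cohort({1: [10, 20, 30], 2: [15, 25, 35]})
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(CohortError, match="duplicate"):
            validate_cohort(dup)

    def test_incomplete_grid_lists_missing_cells(self):
        df = tiny_cohort({1: [10, 20, 30], 2: [15, 25, 35]})
        holey = df.drop(index=[4]).reset_index(drop=True)
        with pytest.raises(CohortError, match="missing cells"):
            validate_cohort(holey)

    def test_out_of_range_percentages_rejected(self):
        df = tiny_cohort({1: [10, 20, 130], 2: [15, 25, 35]})
        with pytest.raises(CohortError, match="outside"):
            validate_cohort(df)


class TestRMAnova:
    def test_matches_from_scratch_sums_of_squares(self):
        # hand fixture, 3 subjects x 3 timepoints of small integers
        df = tiny_cohort({1: [10, 12, 14], 2: [11, 15, 13], 3: [9, 10, 17]})
        res = rm_anova(df, 1)
        # independent oracle: partition SS by subject and timepoint means
        vals = np.array([[10, 12, 14], [11, 15, 13], [9, 10, 17]], dtype=float)
        grand = vals.mean()
        ss_tp = vals.shape[0] * ((vals.mean(0) - grand) ** 2).sum()
        resid = vals - vals.mean(1)[:, None] - vals.mean(0)[None, :] + grand
        ss_err = (resid**2).sum()
        f_manual = (ss_tp / 2) / (ss_err / 4)
        assert res.F == pytest.approx(f_manual)
        # value independently confirmed with R aov(y ~ tp + Error(subject/tp))
        assert res.F == pytest.approx(3.0625, abs=1e-4)
        assert res.p == pytest.approx(0.156074, abs=1e-4)
        assert not res.degenerate

    def test_zero_variance_is_degenerate_with_p_one(self):
        df = tiny_cohort({1: [40, 40, 40], 2: [60, 60, 60], 3: [50, 50, 50]})
        res = rm_anova(df, 1)
        assert res.degenerate and res.p == 1.0

    def test_incomplete_session_grid_raises(self):
        df = tiny_cohort({1: [10, 20, 30], 2: [15, 25, 35]})
        holey = df.drop(index=[5]).reset_index(drop=True)
        with pytest.raises(CohortError, match="incomplete"):
            rm_anova(holey, 1)

    def test_single_subject_rejected(self):
        df = tiny_cohort({1: [10, 20, 30]})
        with pytest.raises(CohortError, match="2 subjects"):
            rm_anova(df, 1)


class TestTukeyPairwise:
    def test_plate_family_reduces_to_paired_t(self):
        # k = 2 studentized-range adjustment equals the two-sided paired t
        from scipy.stats import ttest_1samp

        df = tiny_cohort({1: [30, 20, 55], 2: [35, 25, 60], 3: [20, 35, 45], 4: [28, 22, 52]})
        fam = tukey_pairwise(df, 1, family="plate")
        for tpn in TPS:
            vals = df[df.timepoint == tpn].sort_values("subject")["pct_colder"].to_numpy()
            expected = ttest_1samp(vals - 50.0, 0.0).pvalue
            got = fam.loc[fam.timepoint == tpn, "p_adj"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-9)

    def test_timepoint_family_matches_r_ptukey_oracle(self):
        # frozen from R: t.test paired t = -2.645751 on these cells,
        # ptukey(sqrt(2)*|t|, 3, 2, lower=FALSE) = 0.2067432
        df = tiny_cohort({1: [10, 12, 14], 2: [11, 15, 13], 3: [9, 10, 17]})
        fam = tukey_pairwise(df, 1, family="timepoint")
        row = fam[(fam.level_a == "before_oxa") & (fam.level_b == "pre_drug")]
        assert row["t"].iloc[0] == pytest.approx(2.645751, abs=1e-5)
        assert row["p_adj"].iloc[0] == pytest.approx(0.2067432, abs=1e-6)

    def test_identical_groups_have_p_one(self):
        df = tiny_cohort({1: [40, 40, 10], 2: [60, 60, 20], 3: [55, 55, 30]})
        fam = tukey_pairwise(df, 1, family="timepoint")
        row = fam[(fam.level_a == "before_oxa") & (fam.level_b == "pre_drug")]
        assert row["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_extreme_timepoint_has_smallest_p(self):
        df = tiny_cohort(
            {1: [50, 52, 95], 2: [48, 51, 97], 3: [52, 49, 96], 4: [49, 50, 94]}
        )
        fam = tukey_pairwise(df, 1, family="timepoint")
        involving_post = fam["level_b"] == "post_drug"
        assert fam.loc[involving_post, "p_adj"].max() < fam.loc[~involving_post, "p_adj"].min()

    def test_adjusted_at_least_unadjusted(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(3)
        df = tiny_cohort({s: rng.uniform(20, 80, 3) for s in range(1, 9)})
        fam = tukey_pairwise(df, 1, family="timepoint")
        for _, row in fam.iterrows():
            a = df[df.timepoint == row.level_a].sort_values("subject")["pct_colder"].to_numpy()
            b = df[df.timepoint == row.level_b].sort_values("subject")["pct_colder"].to_numpy()
            assert row.p_adj >= ttest_rel(a, b).pvalue - 1e-12

    def test_unknown_family_rejected(self):
        df = tiny_cohort({1: [1, 2, 3], 2: [4, 5, 6]})
        with pytest.raises(ValueError, match="family"):
            tukey_pairwise(df, 1, family="plates")


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.03, "*"),
            (0.00009, "****"),
            (0.05, "ns"),  # strict inequality at the boundary
            (0.009, "**"),
            (0.0009, "***"),
            (0.2, "ns"),
            (0.0, "****"),
            (1.0, "ns"),
        ],
    )
    def test_threshold_mapping(self, p, expected):
        assert stars(p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.5, float("nan")])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError):
            stars(p)

    @given(
        p=st.floats(0, 1, allow_nan=False),
        q=st.floats(0, 1, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100)
    def test_stars_non_increasing_in_p(self, p, q):
        rank = {"****": 4, "***": 3, "**": 2, "*": 1, "ns": 0}
        lo, hi = sorted((p, q))
        assert rank[stars(lo)] >= rank[stars(hi)]


class TestCallPreference:
    def test_strong_warm_preference(self):
        df = tiny_cohort({s: [20 + s, 22, 80] for s in range(1, 8)})
        call = call_preference(df, 1, "before_oxa")
        assert call.direction == "warmer"
        assert call.p_adj < 0.001

    def test_nonsignificant_is_none(self):
        rng = np.random.default_rng(1)
        df = tiny_cohort({s: 50 + rng.normal(0, 15, 3) for s in range(1, 8)})
        call = call_preference(df, 1, "before_oxa")
        assert call.direction == "none" and call.stars == "ns"

    def test_exact_fifty_fifty_mean_has_no_direction(self):
        # complementary subjects: mean exactly 50 with tiny variance -> none
        df = tiny_cohort({1: [49, 50, 50], 2: [51, 50, 50], 3: [50, 50, 50], 4: [50, 50, 50]})
        call = call_preference(df, 1, "before_oxa")
        assert call.direction == "none"


class TestCallDrugEffect:
    def _call(self, direction, session=1, timepoint="pre_drug"):
        p = 0.001 if direction != "none" else 0.5
        return PreferenceCall(
            session_id=session,
            timepoint=timepoint,
            direction=direction,
            p_adj=p,
            mean_pct_colder=50.0,
            stars=stars(p) if direction != "none" else "ns",
        )

    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            ("warmer", "none", "lost"),
            ("warmer", "colder", "reversed"),
            ("warmer", "warmer", "maintained"),
            ("colder", "warmer", "reversed"),
            ("colder", "colder", "maintained"),
            ("colder", "none", "lost"),
            ("none", "warmer", "no_baseline"),
            ("none", "none", "no_baseline"),
        ],
    )
    def test_categories(self, pre, post, expected):
        call = call_drug_effect(self._call(pre), self._call(post, timepoint="post_drug"))
        assert call.category == expected

    def test_classification_total_over_direction_grid(self):
        # every (pre, post) pair maps to exactly one category
        cats = {"maintained", "lost", "reversed", "no_baseline"}
        for pre, post in itertools.product(["warmer", "colder", "none"], repeat=2):
            call = call_drug_effect(self._call(pre), self._call(post, timepoint="post_drug"))
            assert call.category in cats
            if pre == "none":
                assert call.category == "no_baseline"
            elif post == "none":
                assert call.category == "lost"
            elif pre == post:
                assert call.category == "maintained"
            else:
                assert call.category == "reversed"

    def test_mismatched_sessions_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            call_drug_effect(self._call("warmer", session=1), self._call("none", session=2))


class TestAnalyzeCohort:
    def test_duloxetine_like_cohort_reports_expected_pattern(self):
        coh = tp.simulate_cohort(
            10, tp.standard_protocol(), effects=tp.duloxetine_effects(), seed=42
        )
        calls = analyze_cohort(coh)
        by_session = calls.set_index("session_id")["category"]
        assert by_session[2] == "reversed"
        assert by_session[3] == "maintained"
        assert by_session[1] in ("lost", "reversed")

    def test_null_cohort_rarely_flags_analgesia(self):
        coh = tp.simulate_cohort(
            10, tp.standard_protocol(), agent=tp.AgentParams(beta=0.0), seed=3,
            start_side="random",
        )
        calls = analyze_cohort(coh, omnibus=False)
        flagged = (calls.category.isin(["lost", "reversed"])).sum()
        assert flagged <= 2
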