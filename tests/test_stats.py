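"""Group statistics: Cohen's d, odds ratios, exact tests, cohort comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from camnorms import (
    cohens_d,
    cohens_d_from_values,
    compare_cohort,
    fisher_exact,
    odds_ratio,
    student_t,
)

counts = st.integers(min_value=1, max_value=200)


class TestCohensD:
    def test_equal_means_give_zero(self):
        cc = cohens_d(10.0, 2.0, 30, 10.0, 3.0, 40)
        assert cc.d == 0.0
        assert cc.d_ci[0] < 0 < cc.d_ci[1]

    def test_pooled_sd_formula(self):
        cc = cohens_d(12.0, 2.0, 20, 10.0, 4.0, 10)
        sp = np.sqrt((19 * 4 + 9 * 16) / 28)
        assert cc.d == pytest.approx(2.0 / sp)

    @given(
        st.floats(-5, 5), st.floats(0.5, 3), st.integers(5, 100),
        st.floats(-5, 5), st.floats(0.5, 3), st.integers(5, 100),
    )
    def test_antisymmetry(self, m1, s1, n1, m0, s0, n0):
        a = cohens_d(m1, s1, n1, m0, s0, n0)
        b = cohens_d(m0, s0, n0, m1, s1, n1)
        assert a.d == pytest.approx(-b.d, abs=1e-12)
        assert a.d_ci[0] == pytest.approx(-b.d_ci[1], abs=1e-12)
        assert a.d_ci[0] <= a.d <= a.d_ci[1]

    def test_sign_matches_mean_difference(self):
        assert cohens_d(9.0, 2.0, 30, 10.0, 2.0, 30).d < 0

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            cohens_d(1.0, 1.0, 1, 0.0, 1.0, 30)


class TestOddsRatio:
    def test_unit_table(self):
        assert odds_ratio(10, 10, 10, 10).or_ == pytest.approx(1.0)

    @given(counts, counts, counts, counts)
    def test_swap_invariances(self, a, b, c, d):
        base = odds_ratio(a, b, c, d).or_
        # swapping both rows and both columns leaves the OR unchanged
        assert odds_ratio(d, c, b, a).or_ == pytest.approx(base, rel=1e-12)
        # swapping the rows inverts it
        assert odds_ratio(c, d, a, b).or_ == pytest.approx(1 / base, rel=1e-12)

    def test_wald_ci_contains_estimate(self):
        bc = odds_ratio(30, 70, 20, 80)
        assert bc.or_ci[0] < bc.or_ < bc.or_ci[1]

    def test_profile_ci_contains_estimate(self):
        bc = odds_ratio(30, 70, 20, 80, ci="profile")
        assert bc.or_ci[0] < bc.or_ < bc.or_ci[1]
        wald = odds_ratio(30, 70, 20, 80).or_ci
        # both intervals are 95%; they should be close but not identical
        assert bc.or_ci == pytest.approx(wald, rel=0.15)
        assert bc.or_ci != wald

    def test_zero_cell_continuity_correction(self):
        bc = odds_ratio(0, 20, 5, 15)
        assert bc.continuity_corrected
        assert np.isfinite(bc.or_) and bc.or_ > 0

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            odds_ratio(0, 0, 5, 15)

    def test_matches_logistic_regression_mle(self):
        """The 2x2 OR equals the single-predictor logistic regression MLE."""
        import statsmodels.api as sm

        a, b, c, d = 55, 217, 38, 279
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert odds_ratio(a, b, c, d).or_ == pytest.approx(np.exp(fit.params[1]), rel=1e-6)


class TestFisherExact:
    def test_extreme_table(self):
        # all 2x2 tables with margins (5,5)/(5,5): only the two diagonal
        # extremes are as improbable as the observed one -> p = 2/C(10,5)
        assert fisher_exact(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_balanced_table(self):
        assert fisher_exact(8, 8, 8, 8) == pytest.approx(1.0)

    def test_brute_force_enumeration_small_n(self):
        """Exact agreement with hypergeometric enumeration for all tables, n <= 12."""
        worst = 0.0
        for n in range(1, 13):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                    support = np.arange(lo, hi + 1)
                    pmf = sps.hypergeom.pmf(support, n, r1, c1)
                    for a in support:
                        b, c = r1 - a, c1 - a
                        d = n - r1 - c1 + a
                        expected = pmf[pmf <= pmf[a - lo] * (1 + 1e-7)].sum()
                        worst = max(worst, abs(fisher_exact(a, b, c, d) - expected))
        assert worst < 1e-12


class TestStudentT:
    def test_identical_groups(self):
        x = np.arange(10.0)
        res = student_t(x, x)
        assert res.p == pytest.approx(1.0)
        assert res.diff == 0.0

    def test_published_age_contrast_significant(self):
        res = student_t(stats1=(37.9, 9.38, 347), stats0=(34.6, 10.5, 395))
        assert res.p < 0.001
        assert res.diff == pytest.approx(3.3, abs=1e-9)

    def test_matches_permutation_oracle(self):
        """Pooled t-test p agrees with a permutation test at n=20 per group."""
        rng = np.random.default_rng(321)
        x1 = rng.normal(0.6, 1.0, 20)
        x0 = rng.normal(0.0, 1.0, 20)
        res = student_t(x1, x0)
        pooled = np.concatenate([x1, x0])
        B = 100_000
        perms = rng.permuted(np.tile(pooled, (B, 1)), axis=1)
        diffs = perms[:, :20].mean(axis=1) - perms[:, 20:].mean(axis=1)
        p_perm = np.mean(np.abs(diffs) >= abs(res.diff) - 1e-12)
        assert res.p == pytest.approx(p_perm, abs=0.01)

    def test_type_one_error_calibrated(self):
        """Null rejections at the 5% level occur in 5% +/- 1.5% of replicates."""
        rng = np.random.default_rng(555)
        rejections = 0
        R = 1000
        for _ in range(R):
            x1 = rng.normal(0, 1, 100)
            x0 = rng.normal(0, 1, 100)
            rejections += student_t(x1, x0).p < 0.05
        assert rejections / R == pytest.approx(0.05, abs=0.015)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            student_t(np.ones(5), np.zeros(5))

    def test_mixed_input_forms_rejected(self):
        with pytest.raises(ValueError):
            student_t(x1=np.ones(5), stats0=(0, 1, 5))


@pytest.fixture(scope="module")
def scored(norms, default_spec):
    from camnorms import generate_cohort, score_frame

    return score_frame(generate_cohort(default_spec, seed=17), norms)


class TestCompareCohort:
    def test_hiv_contrast_layout(self, scored):
        rep = compare_cohort(scored)
        assert rep.exposed_label == "hiv_pos"
        assert set(rep.continuous.measure) >= {"ctt2_time", "executive", "verbal"}
        assert {"d", "d_ci_low", "p"} <= set(rep.continuous.columns)
        assert {"or", "or_ci_low", "fisher_p"} <= set(rep.binary.columns)

    def test_cd4_split_is_exactly_350(self, scored):
        rep = compare_cohort(scored, stratifier="cd4_350")
        pos = scored[scored.group == "hiv_pos"]
        n_hi = int((pos.cd4 >= 350).sum())
        assert rep.continuous.n1.max() <= n_hi
        row = rep.continuous.iloc[0]
        assert row.n1 + row.n0 <= len(pos)

    def test_all_builtin_stratifiers_run(self, scored):
        for strat in ("hiv_status", "art_status", "cd4_350", "vl_detectable", "genotype"):
            rep = compare_cohort(scored, stratifier=strat)
            assert len(rep.continuous)

    def test_unknown_stratifier_rejected(self, scored):
        with pytest.raises(KeyError, match="unknown stratifier"):
            compare_cohort(scored, stratifier="nope")

    def test_tiny_stratum_skipped(self, norms, default_spec):
        import dataclasses

        from camnorms import generate_cohort, score_frame

        spec = dataclasses.replace(default_spec, n_neg=1, n_pos=30)
        scored = score_frame(generate_cohort(spec, seed=2), norms)
        rep = compare_cohort(scored)  # reference stratum has 1 subject
        assert rep.continuous.empty

    def test_d_computed_from_values_matches_summary_route(self, scored):
        t1 = scored.loc[scored.group == "hiv_pos", "t_wcst_errors"].dropna()
        t0 = scored.loc[scored.group == "hiv_neg", "t_wcst_errors"].dropna()
        via_values = cohens_d_from_values(t1, t0)
        via_stats = cohens_d(
            t1.mean(), t1.std(ddof=1), len(t1), t0.mean(), t0.std(ddof=1), len(t0)
        )
        assert via_values.d == pytest.approx(via_stats.d, abs=1e-12)
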