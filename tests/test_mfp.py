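"""MFP regression: transforms, closed-test selection, OLS equivalence, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from camnorms.mfp import (
    Demographics,
    FPTerm,
    MFPError,
    MFPModel,
    SingularFitError,
    UnsupportedShapeError,
    default_shift_scale,
    fit_mfp,
    fp_transform,
)


def simulate_linear(rng, n=400, b0=8.0, b_edu=2.0, b_age=-7.0, b_male=0.5, sd=2.5):
    """Scaled scores with a linear demographic gradient (the generative truth
    mirrored by the published formulas)."""
    age = np.clip(rng.normal(34.6, 10.5, n), 18, 64)
    edu = np.clip(np.round(rng.normal(12.4, 4.23, n)), 0, 20)
    male = (rng.random(n) < 0.35).astype(int)
    y = (
        b0
        + b_edu * (edu + 1) / 10
        + b_age * age / 100
        + b_male * male
        + rng.normal(0, sd, n)
    )
    return y, pd.DataFrame({"age": age, "education": edu, "male": male})


class TestTransforms:
    @pytest.mark.parametrize(
        "x, term, expected",
        [
            (12, FPTerm("education", 1.0, shift=1, scale=10), 1.3),
            (35, FPTerm("age", 1.0, shift=0, scale=100), 0.35),
            (99, FPTerm("x", 0.0, shift=1, scale=1), math.log(100)),
            (4, FPTerm("x", -0.5, shift=0, scale=1), 0.5),
        ],
    )
    def test_values(self, x, term, expected):
        assert fp_transform(x, term) == pytest.approx(expected, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(MFPError, match="shift"):
            fp_transform(-2, FPTerm("x", 0.5, shift=1, scale=1))

    def test_repeated_power_convention(self):
        term = FPTerm("x", 2.0, shift=0, scale=1, repeated=True)
        assert fp_transform(3.0, term) == pytest.approx(9 * math.log(3))

    def test_default_shift_scale_education(self):
        shift, scale = default_shift_scale(np.arange(0, 21))
        assert (shift, scale) == (1.0, 10.0)

    def test_default_shift_scale_age(self):
        shift, scale = default_shift_scale(np.linspace(18, 64, 100))
        assert (shift, scale) == (0.0, 100.0)


class TestFixedPowerEquivalence:
    def test_forced_linear_matches_statsmodels_ols(self):
        """With powers fixed at 1, the MFP fit is ordinary least squares."""
        rng = np.random.default_rng(21)
        y, demo = simulate_linear(rng)
        res = MFPModel(y, demo).fit(forced_linear=("education", "age"))
        X = sm.add_constant(
            np.column_stack(
                [(demo["education"] + 1) / 10, demo["age"] / 100, demo["male"]]
            )
        )
        ols = sm.OLS(y, X).fit()
        c = res.canonical_coefficients()  # (edu+1)/10, age/100 basis, as the oracle
        got = np.array([c["const"], c["education"], c["age"], c["male"]])
        assert np.allclose(got, ols.params, atol=1e-8)
        assert res.resid_sd == pytest.approx(np.sqrt(ols.mse_resid), abs=1e-10)
        # slope standard errors are invariant to the positivity shift
        got_se = res.bse[["education^1", "age^1", "male"]].to_numpy()
        assert np.allclose(got_se, np.asarray(ols.bse)[1:], atol=1e-8)


class TestSelection:
    def test_linear_truth_selects_linear_and_recovers(self):
        rng = np.random.default_rng(99)
        y, demo = simulate_linear(rng)
        res = fit_mfp(y, demo)
        assert res.selection["education"] == (1.0,)
        assert res.selection["age"] == (1.0,)
        c = res.canonical_coefficients()
        truth = {"const": 8.0, "education": 2.0, "age": -7.0, "male": 0.5}
        se = {
            "const": res.bse["const"],
            "education": res.bse["education^1"],
            "age": res.bse["age^1"],
            "male": res.bse["male"],
        }
        for k, v in truth.items():
            assert abs(c[k] - v) < 3 * se[k], k

    def test_quadratic_age_effect_detected(self):
        """A genuinely curved age effect rejects the linear shape in most runs."""
        nonlinear = 0
        for r in range(11):
            rng = np.random.default_rng(300 + r)
            n = 1000
            age = np.clip(rng.normal(40, 11, n), 18, 64)
            edu = np.clip(np.round(rng.normal(12, 4, n)), 0, 20)
            male = (rng.random(n) < 0.35).astype(int)
            y = 10 + 25 * (age / 100) ** 2 + rng.normal(0, 2.5, n)
            demo = pd.DataFrame({"age": age, "education": edu, "male": male})
            res = fit_mfp(y, demo)
            nonlinear += res.selection["age"] not in (None, (1.0,))
        assert nonlinear > 11 // 2

    def test_null_covariates_dropped_at_nominal_level(self):
        """Type-I control of the closed test: pure-noise covariates are dropped
        in at least 90% of replicates at alpha = 0.05."""
        R = 200
        both = 0
        for r in range(R):
            rng = np.random.default_rng(4000 + r)
            n = 400
            age = np.clip(rng.normal(34.6, 10.5, n), 18, 64)
            edu = np.clip(np.round(rng.normal(12.4, 4.23, n)), 0, 20)
            male = (rng.random(n) < 0.35).astype(int)
            y = rng.normal(10, 3, n)
            demo = pd.DataFrame({"age": age, "education": edu, "male": male})
            res = fit_mfp(y, demo)
            both += (res.selection["education"] is None) and (
                res.selection["age"] is None
            )
        assert both / R >= 0.90

    def test_refuses_small_sample(self):
        rng = np.random.default_rng(1)
        y, demo = simulate_linear(rng, n=30)
        with pytest.raises(MFPError, match="observations"):
            MFPModel(y, demo)

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(2)
        y, demo = simulate_linear(rng)
        demo = demo.copy()
        demo["age"] = demo["education"]  # age == education -> singular design
        with pytest.raises(SingularFitError):
            MFPModel(y, demo).fit()


class TestEmission:
    def test_emitted_coefficients_reproduce_predictions(self):
        rng = np.random.default_rng(31)
        y, demo = simulate_linear(rng)
        res = MFPModel(y, demo).fit(forced_linear=("education", "age"))
        coef = res.to_norm_coefficients("ctt2_time")
        pred = coef.predict_ss(demo["age"], demo["education"], demo["male"])
        assert np.allclose(pred, res.predict(demo), atol=1e-10)
        z = (y - pred) / coef.resid_sd
        assert abs(z.mean()) < 1e-10
        n_params = len(res.params)
        sd = np.sqrt((z**2).sum() / (len(y) - n_params))
        assert sd == pytest.approx(1.0, abs=1e-6)

    def test_emitted_t_scores_centered_and_decorrelated(self):
        """T-scores on the fitting sample: mean 50, SD 10, no demographic trend."""
        rng = np.random.default_rng(17)
        y, demo = simulate_linear(rng)
        res = fit_mfp(y, demo)
        t = res.t_scores()
        assert t.mean() == pytest.approx(50.0, abs=0.2)
        assert t.std(ddof=1) == pytest.approx(10.0, abs=0.3)
        for col in ("age", "education", "male"):
            assert abs(np.corrcoef(t, demo[col])[0, 1]) < 0.05

    def test_nonlinear_shape_refuses_emission(self):
        rng = np.random.default_rng(44)
        n = 1000
        age = np.clip(rng.normal(40, 11, n), 18, 64)
        edu = np.clip(np.round(rng.normal(12, 4, n)), 0, 20)
        male = (rng.random(n) < 0.35).astype(int)
        y = 10 + 60 * (age / 100) ** 2 + rng.normal(0, 2.0, n)
        res = fit_mfp(y, pd.DataFrame({"age": age, "education": edu, "male": male}))
        assert res.selection["age"] not in (None, (1.0,))
        with pytest.raises(UnsupportedShapeError, match="age"):
            res.canonical_coefficients()

    def test_dropped_covariate_emits_zero_slope(self):
        rng = np.random.default_rng(50)
        y, demo = simulate_linear(rng, b_age=0.0)  # no real age effect
        res = fit_mfp(y, demo)
        if res.selection["age"] is None:
            coef = res.to_norm_coefficients("hct_errors")
            assert coef.b_age == 0.0


class TestBootstrap:
    def test_single_replicate_degenerate_frequencies(self):
        rng = np.random.default_rng(8)
        y, demo = simulate_linear(rng)
        res = fit_mfp(y, demo)
        report = res.bootstrap_stability(K=1, seed=0)
        for freqs in report.power_frequencies.values():
            assert all(f in (0.0, 1.0) for f in freqs.values())

    def test_same_seed_identical_reports(self):
        rng = np.random.default_rng(9)
        y, demo = simulate_linear(rng)
        res = fit_mfp(y, demo)
        r1 = res.bootstrap_stability(K=8, seed=123)
        r2 = res.bootstrap_stability(K=8, seed=123)
        assert r1.power_frequencies == r2.power_frequencies
        pd.testing.assert_frame_equal(r1.coef_summary, r2.coef_summary)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(10)
        y, demo = simulate_linear(rng)
        res = fit_mfp(y, demo)
        report = res.bootstrap_stability(K=20, seed=5)
        for freqs in report.power_frequencies.values():
            assert sum(freqs.values()) == pytest.approx(1.0)

    def test_linear_truth_stable_under_bootstrap(self):
        """Education stays linear in at least 85% of bootstrap refits."""
        rng = np.random.default_rng(11)
        y, demo = simulate_linear(rng)
        res = fit_mfp(y, demo)
        report = res.bootstrap_stability(K=200, seed=77)
        assert report.power_frequencies["education"].get("1", 0.0) >= 0.85
        assert "Bootstrap stability" in report.summary()


def test_fit_mfp_accepts_demographics_objects():
    rng = np.random.default_rng(13)
    y, demo = simulate_linear(rng, n=120)
    objs = [
        Demographics(a, e, m)
        for a, e, m in zip(demo["age"], demo["education"], demo["male"])
    ]
    res = fit_mfp(y, objs)
    assert res.nobs == 120
    assert "MFP demographic-correction model" in res.summary()
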