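import json
import shutil
import subprocess
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import agemeta.metamodels as mm
from agemeta.studyfit import StudySummary
from conftest import make_summaries


def summ(betas, ses, ages=None, sds=None):
    ages = ages if ages is not None else [30.0] * len(betas)
    sds = sds if sds is not None else [5.0] * len(betas)
    return [
        StudySummary(str(i), float(b), float(s), 1000, float(a), float(sd))
        for i, (b, s, a, sd) in enumerate(zip(betas, ses, ages, sds))
    ]


def grid_reml(y, v, X, hi=10.0, step=1e-4):
    """Brute-force restricted-likelihood maximiser over a tau2 grid."""
    grid = np.arange(0.0, hi + step, step)
    vals = [mm._neg_restricted_ll(t, y, v, X) for t in grid]
    return grid[int(np.argmin(vals))]


class TestFixedEffect:
    def test_two_study_symmetric_closed_form(self):
        fit = mm.fixed_effect_ma(summ([1.0, 3.0], [1.0, 1.0]))
        assert fit.estimate == pytest.approx(2.0)
        assert fit.se[0] == pytest.approx(1 / np.sqrt(2))
        assert fit.ci_low[0] == pytest.approx(2.0 - 1.96 / np.sqrt(2))

    def test_single_study_rejected(self):
        with pytest.raises(mm.InsufficientStudiesError):
            mm.fixed_effect_ma(summ([1.0], [1.0]))

    def test_five_study_fixture_vs_exact_rational_oracle(self):
        betas = [Fraction(3, 2), Fraction(7, 5), Fraction(9, 4),
                 Fraction(1, 2), Fraction(11, 10)]
        ses = [Fraction(1, 10), Fraction(1, 5), Fraction(3, 20),
               Fraction(2, 5), Fraction(1, 4)]
        w = [1 / s**2 for s in ses]
        exact = sum(wi * b for wi, b in zip(w, betas)) / sum(w)
        fit = mm.fixed_effect_ma(summ([float(b) for b in betas],
                                      [float(s) for s in ses]))
        assert fit.estimate == pytest.approx(float(exact), rel=1e-14)
        assert fit.se[0] == pytest.approx(float(1 / sum(w)) ** 0.5, rel=1e-14)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_splitting_a_study(self, seed):
        rng = np.random.default_rng(seed)
        betas = rng.normal(1.5, 0.5, 5)
        ses = rng.uniform(0.1, 0.5, 5)
        full = mm.fixed_effect_ma(summ(betas, ses))
        # split study 0 into two halves with the same effect and weights
        # summing to the original: w0 = w0/2 + w0/2
        split_ses = np.concatenate([[ses[0] * np.sqrt(2), ses[0] * np.sqrt(2)], ses[1:]])
        split_betas = np.concatenate([[betas[0], betas[0]], betas[1:]])
        split = mm.fixed_effect_ma(summ(split_betas, split_ses))
        assert split.estimate == pytest.approx(full.estimate, rel=1e-12)
        assert split.se[0] == pytest.approx(full.se[0], rel=1e-12)


class TestReml:
    def test_identical_effects_give_zero_tau2(self):
        y = np.full(6, 1.3)
        v = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        assert mm.reml_tau2(y, v, np.ones((6, 1))) == 0.0

    def test_matches_grid_search_on_inflated_fixture(self):
        rng = np.random.default_rng(1)
        y = 1.5 + rng.normal(0, 1.0, 6)
        v = rng.uniform(0.01, 0.1, 6)
        X = np.ones((6, 1))
        tau2 = mm.reml_tau2(y, v, X)
        assert tau2 == pytest.approx(grid_reml(y, v, X), abs=2e-4)

    def test_needs_more_studies_than_parameters(self):
        with pytest.raises(mm.InsufficientStudiesError):
            mm.reml_tau2(np.ones(2), np.ones(2), np.ones((2, 2)))

    def test_scenario_level_tau2_recovery(self):
        # k studies whose true effects deviate with SD 1: tau2-hat near 1
        rng = np.random.default_rng(7)
        reps = [
            mm.reml_tau2(
                1.5 + rng.normal(0, 1.0, 40) + rng.normal(0, 0.08, 40),
                np.full(40, 0.08**2),
                np.ones((40, 1)),
            )
            for _ in range(60)
        ]
        mc_se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert np.mean(reps) == pytest.approx(1.0, abs=4 * mc_se + 0.02)


class TestRandomEffects:
    def test_zero_tau2_reduces_to_fixed(self):
        studies = summ([1.3] * 5, [0.1, 0.2, 0.3, 0.15, 0.25])
        fe, re = mm.fixed_effect_ma(studies), mm.random_effects_ma(studies)
        assert re.tau2 == 0.0
        assert re.estimate == pytest.approx(fe.estimate, rel=1e-12)
        assert re.se[0] == pytest.approx(fe.se[0], rel=1e-12)

    def test_two_study_symmetry_regardless_of_tau2(self):
        fit = mm.random_effects_ma(summ([0.0, 4.0], [1.0, 1.0]))
        assert fit.estimate == pytest.approx(2.0)

    def test_re_se_never_below_fe_se(self):
        for seed in range(10):
            studies = make_summaries(seed=seed)
            fe, re = mm.fixed_effect_ma(studies), mm.random_effects_ma(studies)
            assert re.se[0] >= fe.se[0] - 1e-12


class TestAgeMoments:
    def test_printed_identity_example(self):
        m = mm.derive_age_moments(30.0, 5.0, centre=10.0, degree=2)
        assert m[0] == 20.0
        assert m[1] == 425.0  # sd^2 + (mean-centre)^2 = 25 + 400

    def test_point_mass_reduces_to_pure_powers(self):
        m = mm.derive_age_moments(7.0, 0.0, centre=2.0, degree=3)
        assert np.allclose(m, [5.0, 25.0, 125.0])

    def test_uniform_window_closed_form_moments(self):
        # Uniform[a,b]: variance w^2/12, third central moment 0, so the
        # zero-skewness derivation is exact
        a, b, c = 12.0, 28.0, 10.0
        mean, var = (a + b) / 2, (b - a) ** 2 / 12
        m = mm.derive_age_moments(mean, np.sqrt(var), centre=c, degree=3)
        d = mean - c
        exact_m2 = var + d**2
        exact_m3 = d**3 + 3 * d * var  # + E[(age-mean)^3] = 0
        assert m[1] == pytest.approx(exact_m2, rel=1e-12)
        assert m[2] == pytest.approx(exact_m3, rel=1e-12)

    def test_explicit_third_moment_override(self):
        # a two-point age distribution is skewed: supplying mean(age^3)
        # must reproduce the exact centred third moment
        ages = np.array([10.0, 10.0, 40.0])
        mean, sd = ages.mean(), ages.std(ddof=1)
        raw3 = float((ages**3).mean())
        c = 5.0
        m = mm.derive_age_moments(mean, sd, centre=c, degree=3, mean_age3=raw3)
        # n-1 vs n convention for sd^2 leaves a small known slack
        exact = ((ages - c) ** 3).mean()
        assert m[2] == pytest.approx(exact, rel=0.2)
        assert abs(m[2] - exact) < abs(
            mm.derive_age_moments(mean, sd, centre=c, degree=3)[2] - exact
        )

    def test_unsupported_degree(self):
        with pytest.raises(ValueError):
            mm.derive_age_moments(30.0, 5.0, degree=4)


class TestMetaRegression:
    def test_degree0_equals_random_effects(self):
        studies = make_summaries(seed=3)
        re = mm.random_effects_ma(studies)
        mr = mm.meta_regression(studies, degree=0, centre=10.0)
        assert mr.estimate == pytest.approx(re.estimate, rel=1e-12)
        assert mr.tau2 == pytest.approx(re.tau2, rel=1e-9)

    def test_noiseless_linear_fixture_exact_recovery(self):
        ages = np.array([15.0, 25.0, 35.0, 45.0, 55.0])
        beta_snp, slope, c = 1.5, 0.02, 10.0
        y = beta_snp + slope * (ages - c)
        studies = summ(y, [1e-4] * 5, ages=ages, sds=[3.0] * 5)
        fit = mm.meta_regression(studies, degree=1, centre=c)
        assert fit.coef[0] == pytest.approx(beta_snp, rel=1e-9)
        assert fit.coef[1] == pytest.approx(slope, rel=1e-9)
        assert fit.tau2 == pytest.approx(0.0, abs=1e-10)

    def test_collinear_mean_ages_raise_named_error(self):
        studies = summ([1.0, 1.2, 1.4, 1.1], [0.1] * 4, ages=[30.0] * 4)
        with pytest.raises(mm.CollinearityError, match="beta_snp_age"):
            mm.meta_regression(studies, degree=1, centre=10.0)

    def test_needs_enough_studies(self):
        studies = summ([1.0, 1.2], [0.1, 0.1], ages=[20.0, 40.0])
        with pytest.raises(mm.InsufficientStudiesError):
            mm.meta_regression(studies, degree=1)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_metafor_reml_meta_regression(self):
        studies = make_summaries(seed=11)
        fit = mm.meta_regression(studies, degree=1, centre=10.0)
        y = ",".join(str(s.beta1) for s in studies)
        v = ",".join(str(s.se**2) for s in studies)
        m1 = ",".join(str(s.mean_age - 10.0) for s in studies)
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(c({y}), c({v}), mods=~c({m1}), method='REML',"
            "control=list(tol=1e-10));"
            "cat(jsonlite::toJSON(list(b=as.numeric(r$b), se=as.numeric(r$se),"
            "tau2=r$tau2, QE=r$QE), digits=12))"
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout.strip().splitlines()[-1])
        np.testing.assert_allclose(fit.coef, ref["b"], rtol=1e-4)
        np.testing.assert_allclose(fit.se, ref["se"], rtol=1e-4)
        assert fit.tau2 == pytest.approx(ref["tau2"][0], rel=1e-3, abs=1e-6)
        assert fit.Q == pytest.approx(ref["QE"][0], rel=1e-6)


class TestRecentre:
    def test_linear_intercept_shift_identity(self):
        studies = make_summaries(seed=5)
        f10 = mm.meta_regression(studies, degree=1, centre=10.0)
        f0 = mm.recentre(f10, studies, 0.0)
        assert f0.coef[0] == pytest.approx(
            f10.coef[0] - 10.0 * f10.coef[1], rel=1e-6
        )

    def test_interaction_terms_invariant_across_centres(self):
        studies = make_summaries(seed=8)
        f_a = mm.meta_regression(studies, degree=2, centre=0.0)
        f_b = mm.recentre(f_a, studies, 25.0)
        assert f_b.coef[2] == pytest.approx(f_a.coef[2], abs=1e-10)
        assert f_b.coef[1] == pytest.approx(
            f_a.coef[1] + 2 * 25.0 * f_a.coef[2], abs=1e-8
        )

    def test_intercept_se_minimised_at_weighted_mean_age(self):
        # the GLS intercept variance is minimised when the centred moderator is
        # orthogonal to the intercept, i.e. at the weight-weighted mean age
        # (weights 1/(s_j^2 + tau2) under the random-effects model)
        studies = make_summaries(seed=2)
        base = mm.meta_regression(studies, degree=1, centre=10.0)
        w = np.array([1.0 / (s.se**2 + base.tau2) for s in studies])
        a = np.array([s.mean_age for s in studies])
        re_wma = float(np.sum(w * a) / np.sum(w))
        centres = np.linspace(10.0, 55.0, 91)
        ses = [
            mm.meta_regression(studies, degree=1, centre=c).se[0] for c in centres
        ]
        best = centres[int(np.argmin(ses))]
        assert abs(best - re_wma) <= (centres[1] - centres[0])
        # and it is within a couple of years of the sampling-variance-weighted
        # mean age used as the centring convention
        assert abs(best - mm.weighted_mean_age(studies)) < 5.0

    def test_recentre_requires_metareg(self):
        fit = mm.fixed_effect_ma(summ([1.0, 2.0], [0.1, 0.1]))
        with pytest.raises(ValueError):
            mm.recentre(fit, [], 0.0)


class TestHeterogeneity:
    def test_zero_residuals_zero_q(self):
        fit = mm.fixed_effect_ma(summ([2.0] * 4, [0.5] * 4))
        Q, I2 = mm.heterogeneity(fit)
        assert Q == pytest.approx(0.0, abs=1e-20)
        assert I2 == 0.0

    def test_q_equal_df_boundary(self):
        # two studies, s=1, y = 0 and sqrt(2): Q = 1 = df, I2 = 0
        fit = mm.fixed_effect_ma(summ([0.0, np.sqrt(2.0)], [1.0, 1.0]))
        assert fit.Q == pytest.approx(1.0)
        assert fit.I2 == pytest.approx(0.0)

    def test_q_four_times_df_gives_75pct(self):
        # y = 0, 2*sqrt(2): Q = 2 + 2 = 4 = 4*df, I2 = 75%
        fit = mm.fixed_effect_ma(summ([0.0, 2 * np.sqrt(2.0)], [1.0, 1.0]))
        assert fit.Q == pytest.approx(4.0)
        assert fit.I2 == pytest.approx(75.0)

    def test_undefined_without_residual_df(self):
        # fitting preconditions guarantee df >= 1, so a saturated fit can only
        # arise from external metadata; heterogeneity must refuse it
        fit = mm.meta_regression(
            summ([1.0, 1.5, 2.0, 1.2], [0.1] * 4, ages=[20.0, 30.0, 40.0, 50.0]),
            degree=1,
        )
        fit.df = 0
        with pytest.raises(ValueError):
            mm.heterogeneity(fit)


class TestPrediction:
    def test_linear_polynomial_evaluation(self):
        studies = make_summaries(seed=4)
        fit = mm.meta_regression(studies, degree=1, centre=0.0)
        fit.coef = np.array([1.0, 0.5])
        curve = mm.predict_effect_at_age(fit, [4.0])
        assert curve["effect"].iloc[0] == pytest.approx(3.0)

    def test_prediction_at_centre_is_intercept(self):
        studies = make_summaries(seed=4)
        fit = mm.meta_regression(studies, degree=2, centre=10.0)
        curve = mm.predict_effect_at_age(fit, [10.0])
        assert curve["effect"].iloc[0] == pytest.approx(fit.coef[0], rel=1e-12)
        assert curve["se"].iloc[0] == pytest.approx(fit.se[0], rel=1e-12)

    def test_extrapolation_flagged(self):
        studies = make_summaries(seed=4, age_lo=20.0, age_hi=50.0)
        fit = mm.meta_regression(studies, degree=1, centre=10.0)
        curve = mm.predict_effect_at_age(fit, [5.0, 30.0, 70.0])
        assert curve["extrapolated"].tolist() == [True, False, True]


class TestSerialisation:
    def test_metafit_json_round_trip(self, tmp_path):
        fit = mm.meta_regression(make_summaries(seed=6), degree=2, centre=10.0)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = mm.MetaFit.from_json(path)
        np.testing.assert_allclose(back.coef, fit.coef)
        np.testing.assert_allclose(back.cov, fit.cov)
        assert back.model == fit.model and back.tau2 == fit.tau2

    def test_text_report_mentions_all_terms(self):
        fit = mm.meta_regression(make_summaries(seed=6), degree=2, centre=10.0)
        report = fit.text_report()
        for name in ("beta_snp", "beta_snp_age", "beta_snp_age2", "tau^2", "I^2"):
            assert name in report


def test_knapp_hartung_widens_small_sample_intervals():
    studies = make_summaries(seed=9, k=6)
    plain = mm.meta_regression(studies, degree=1, centre=10.0)
    kh = mm.meta_regression(studies, degree=1, centre=10.0, knapp_hartung=True)
    assert (kh.ci_high[0] - kh.ci_low[0]) >= (plain.ci_high[0] - plain.ci_low[0])


def test_weighted_mean_age_is_inverse_variance_weighted():
    studies = summ([1.0, 1.0], [0.1, 0.2], ages=[20.0, 50.0])
    w1, w2 = 1 / 0.01, 1 / 0.04
    assert mm.weighted_mean_age(studies) == pytest.approx(
        (20 * w1 + 50 * w2) / (w1 + w2)
    )
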