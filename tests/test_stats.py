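"""ANOVA/Tukey letters, paired tests, OLS, and exhaustive GLM selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hydrotraits.reference import REFERENCE_TRAITS
from hydrotraits.stats import (
    anova_tukey,
    enumerate_models,
    fit_glm,
    fit_lm_single,
    paired_t,
    rank_models,
    run_model_selection,
    select_best,
)


class TestAnovaTukey:
    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        groups = {
            "lo": rng.normal(0, 0.1, 5),
            "hi": rng.normal(10, 0.1, 5),
        }
        res = anova_tukey(groups)
        assert res.p_value < 1e-6
        assert set(res.letters["lo"]).isdisjoint(res.letters["hi"])

    def test_identical_means_share_a_letter(self):
        shared = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = {g: rng.normal(0, 1, 6) for g in "abc"}
            res = anova_tukey(groups)
            pairs = [("a", "b"), ("a", "c"), ("b", "c")]
            if all(set(res.letters[x]) & set(res.letters[y]) for x, y in pairs):
                shared += 1
        assert shared >= 18  # all-null groups share letters almost always

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"only": np.array([1.0, 2.0])})

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            anova_tukey({"a": np.array([1.0, 1.0]), "b": np.array([1.0, 1.0])})

    def test_type_i_error_near_nominal(self):
        rejections = 0
        n_sims = 300
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            groups = {g: rng.normal(0, 1, 8) for g in "abc"}
            if anova_tukey(groups).p_value < 0.05:
                rejections += 1
        rate = rejections / n_sims
        ci = 3 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < ci


class TestPairedT:
    def test_identical_vectors(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_with_no_variance_is_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            paired_t([1.0, 2.0], [2.0, 1.0])

    def test_power_against_noncentral_t(self):
        # shift 10, sd 5, n = 10: noncentrality 6.32, power ~ 0.999
        nc = 10 / (5 / np.sqrt(10))
        tcrit = sps.t.ppf(0.975, df=9)
        power = 1 - sps.nct.cdf(tcrit, df=9, nc=nc) + sps.nct.cdf(-tcrit, df=9, nc=nc)
        rejections = 0
        n_sims = 300
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            base = rng.normal(0, 1, 10)
            t, p = paired_t(base + 10 + rng.normal(0, 5, 10), base)
            rejections += p < 0.05
        assert abs(rejections / n_sims - power) < 0.05


class TestSingleTraitLM:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = fit_lm_single(x, 2 * x)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_tlp_declines_with_log_elastic_modulus(self):
        # species with more rigid cell walls lose turgor at more negative psi
        res = fit_lm_single(np.log(REFERENCE_TRAITS["eps"]), REFERENCE_TRAITS["tlp"])
        assert res.r2 == pytest.approx(0.73, abs=0.01)
        assert res.slope < 0
        assert res.p_value < 0.05

    def test_independent_noise_has_near_zero_r2(self):
        rng = np.random.default_rng(3)
        res = fit_lm_single(rng.normal(size=2000), rng.normal(size=2000))
        assert res.r2 < 0.01

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_lm_single([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEnumerateModels:
    def test_binomial_counts_up_to_three_predictors(self):
        formulas = enumerate_models([f"t{i}" for i in range(8)], max_k=3)
        assert len(formulas) == 8 + 28 + 56

    def test_single_predictor(self):
        assert enumerate_models(["x"]) == [("x",)]

    def test_full_power_set_minus_empty(self):
        assert len(enumerate_models(list("abcd"), max_k=10)) == 2**4 - 1

    def test_deterministic_order(self):
        a = enumerate_models(list("abc"), max_k=2)
        assert a == [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")]


def make_xy(n=200, beta=0.5, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 2, n)
    y = np.exp(1.0 + beta * x) + rng.normal(0, noise, n)
    return pd.DataFrame({"x": x}), y


class TestGLM:
    def test_intercept_only_fit_explains_nothing(self):
        X, y = make_xy()
        fit = fit_glm(y, X, formula=())
        assert fit.mcfadden_r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-12)

    def test_log_link_coefficient_recovery(self):
        X, y = make_xy(n=200, beta=0.5, seed=1)
        fit = fit_glm(y, X, clamp=None)
        assert abs(fit.coefficients["x"] - 0.5) < 2 * fit.coefficient_se["x"]

    def test_duplicate_predictors_are_singular(self):
        X, y = make_xy()
        X2 = X.assign(x2=X["x"])
        with pytest.raises(ValueError, match="singular"):
            fit_glm(y, X2, formula=("x", "x2"))

    def test_saturated_regime_flagged_at_five_observations(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(1, 2, size=(5, 3)), columns=list("abc"))
        y = np.exp(1 + X.sum(axis=1) / 10) + rng.normal(0, 0.01, 5)
        fit = fit_glm(y, X)
        assert fit.saturated

    def test_single_predictor_vif_is_one_by_convention(self):
        X, y = make_xy()
        assert fit_glm(y, X).vif == {"x": 1.0}


class TestRanking:
    @staticmethod
    def fits_with_aics(aics):
        from hydrotraits.stats import GLMFit

        return [
            GLMFit(
                formula=(f"p{i}",), coefficients={}, coefficient_se={},
                aic=float(a), mcfadden_r2=0.5, deviance_explained=0.5,
                vif={f"p{i}": 1.0}, n=10,
            )
            for i, a in enumerate(aics)
        ]

    def test_equal_aic_splits_weights_evenly(self):
        ranking = rank_models(self.fits_with_aics([100.0, 100.0]))
        assert [f.akaike_weight for f in ranking.fits] == pytest.approx([0.5, 0.5])

    def test_delta_two_gives_weight_ratio_e(self):
        ranking = rank_models(self.fits_with_aics([10.0, 12.0]))
        w = [f.akaike_weight for f in ranking.fits]
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-6)
        assert w[1] == pytest.approx(0.269, abs=1e-3)

    def test_weights_invariant_under_aic_translation(self):
        a = rank_models(self.fits_with_aics([3.0, 5.0, 9.0]))
        b = rank_models(self.fits_with_aics([103.0, 105.0, 109.0]))
        for fa, fb in zip(a.fits, b.fits):
            assert fa.akaike_weight == pytest.approx(fb.akaike_weight, abs=1e-12)
            assert fa.delta_aic == pytest.approx(fb.delta_aic, abs=1e-12)

    def test_weights_sum_to_one(self):
        ranking = rank_models(self.fits_with_aics([1.0, 4.0, 4.5, 30.0]))
        assert sum(f.akaike_weight for f in ranking.fits) == pytest.approx(1.0, abs=1e-12)
        assert ranking.fits[0].delta_aic == 0.0


class TestSelection:
    def test_orthogonal_predictors_have_unit_vif(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(size=(64, 3))
        q, _ = np.linalg.qr(np.column_stack([np.ones(64), raw]))
        X = pd.DataFrame(q[:, 1:], columns=list("abc"))
        y = np.exp(1 + X["a"]) + rng.normal(0, 0.05, 64)
        fit = fit_glm(y, X, clamp=None)
        for v in fit.vif.values():
            assert v == pytest.approx(1.0, abs=1e-8)

    def test_collinear_best_model_excluded_runner_up_selected(self):
        rng = np.random.default_rng(6)
        n = 40
        x1 = rng.uniform(0, 2, n)
        delta = rng.normal(0, 0.01, n)
        x2 = x1 + delta  # near-duplicate predictor, VIF >> 10
        X = pd.DataFrame({"x1": x1, "x2": x2})
        # the response loads on the tiny x2 - x1 contrast, so the collinear
        # pair wins on AIC but must be excluded on VIF
        y = np.exp(1 + 0.5 * x1 + 20.0 * delta) + rng.normal(0, 0.05, n)
        ranking = run_model_selection(y, X, max_k=2, clamp=None)
        excluded = [f for f in ranking.fits if f.excluded]
        assert any("VIF" in (f.exclusion_reason or "") for f in excluded)
        assert max(ranking.best.vif.values()) <= 10
        assert len(ranking.best.formula) == 1

    def test_no_passing_model_raises_with_vifs(self):
        fits = TestRanking.fits_with_aics([1.0, 2.0])
        for f in fits:
            f.vif = {f.formula[0]: 99.0}
        ranking = rank_models(fits)
        with pytest.raises(ValueError, match="VIF"):
            select_best(ranking, vif_threshold=10.0)
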