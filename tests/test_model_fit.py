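"""GLM fits vs an independent solver, information criteria, and the
covariate-adjusted out-of-sample R² definitions."""

import numpy as np
import pytest
import statsmodels.api as sm

from htrx import (
    PhenotypeTable,
    fit_glm,
    information_criterion,
    null_fit,
    out_of_sample_r2,
)
from htrx.model_fit import predict


class TestLinearFit:
    def test_exact_line_recovered(self):
        x = np.arange(6, dtype=float)
        pheno = PhenotypeTable(2.0 * x, family="linear")
        m = fit_glm(x, pheno, feature_names=["f"])
        np.testing.assert_allclose(m.coef, [0.0, 2.0], atol=1e-10)

    def test_matches_independent_ols(self, rng):
        n = 200
        X = rng.standard_normal((n, 3))
        cov = rng.standard_normal((n, 1))
        y = X @ [1.0, -0.5, 0.2] + cov[:, 0] + rng.standard_normal(n)
        pheno = PhenotypeTable(y, cov, "linear")
        m = fit_glm(X, pheno)
        ref = sm.OLS(y, np.column_stack([np.ones(n), cov, X])).fit()
        np.testing.assert_allclose(m.coef, ref.params, rtol=1e-8)
        # same Gaussian ML loglik convention
        assert m.loglik == pytest.approx(ref.llf, rel=1e-8)

    def test_rank_deficiency_flagged_not_fatal(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, x])  # perfectly collinear
        pheno = PhenotypeTable(x + rng.standard_normal(50), family="linear")
        m = fit_glm(X, pheno)
        assert m.degenerate
        assert np.isfinite(m.loglik)


class TestLogisticFit:
    def test_matches_independent_logit(self, rng):
        n = 500
        X = rng.standard_normal((n, 2))
        eta = 0.5 + X @ [1.0, -1.0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pheno = PhenotypeTable(y, family="logistic")
        m = fit_glm(X, pheno)
        ref = sm.Logit(y, np.column_stack([np.ones(n), X])).fit(disp=0)
        np.testing.assert_allclose(m.coef, ref.params, rtol=1e-5, atol=1e-6)
        assert m.loglik == pytest.approx(ref.llf, rel=1e-8)

    def test_null_feature_coefficient_shrinks_with_n(self, rng):
        coefs = []
        for n in (200, 20000):
            x = rng.standard_normal(n)
            y = (rng.random(n) < 0.3).astype(float)
            m = fit_glm(x, PhenotypeTable(y, family="logistic"))
            coefs.append(abs(m.coef[1]))
        assert coefs[1] < coefs[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_glm(np.ones(10), PhenotypeTable(np.ones(10), family="logistic"))


class TestInformationCriteria:
    def test_aic_bic_penalty_gap(self, rng):
        n = 40
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        pheno = PhenotypeTable(y, family="linear")
        m1 = fit_glm(x, pheno)
        # same loglik, one extra (duplicated) parameter
        m2 = fit_glm(np.column_stack([x, x]), pheno)
        assert m2.loglik == pytest.approx(m1.loglik, abs=1e-6)
        gap_aic = information_criterion(m2, "aic") - information_criterion(m1, "aic")
        gap_bic = information_criterion(m2, "bic") - information_criterion(m1, "bic")
        assert gap_aic == pytest.approx(2.0, abs=1e-5)
        assert gap_bic == pytest.approx(np.log(n), abs=1e-5)

    def test_hand_computed_six_point_fixture(self):
        # y = (0,1,2,3,4,10), x = (0..5): hand least squares
        x = np.arange(6.0)
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 10.0])
        pheno = PhenotypeTable(y, family="linear")
        m = fit_glm(x, pheno)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        rss = np.sum((y - (y.mean() + slope * (x - x.mean()))) ** 2)
        ll = -0.5 * 6 * (np.log(2 * np.pi * rss / 6) + 1)
        assert m.loglik == pytest.approx(ll, rel=1e-10)
        assert information_criterion(m, "aic") == pytest.approx(2 * 3 - 2 * ll)
        assert information_criterion(m, "bic") == pytest.approx(3 * np.log(6) - 2 * ll)

    def test_intercept_only_model(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = null_fit(PhenotypeTable(y, family="linear"))
        rss = np.sum((y - y.mean()) ** 2)
        ll = -0.5 * 4 * (np.log(2 * np.pi * rss / 4) + 1)
        assert information_criterion(m, "aic") == pytest.approx(2 * 2 - 2 * ll)


class TestOutOfSampleR2:
    def _split(self, rng, n=400):
        X = rng.standard_normal((n, 2))
        y = X @ [1.0, 0.5] + 0.5 * rng.standard_normal(n)
        half = n // 2
        tr = PhenotypeTable(y[:half], family="linear")
        te = PhenotypeTable(y[half:], family="linear")
        return X[:half], tr, X[half:], te

    def test_perfect_prediction_gives_one(self):
        x = np.arange(10.0)
        pheno = PhenotypeTable(3.0 * x, family="linear")
        m = fit_glm(x, pheno)
        nullm = null_fit(pheno)
        assert out_of_sample_r2(m, nullm, x, pheno) == pytest.approx(1.0, abs=1e-8)

    def test_null_model_scores_zero(self, rng):
        Xtr, tr, Xte, te = self._split(rng)
        nullm = null_fit(tr)
        assert out_of_sample_r2(nullm, nullm, None, te) == 0.0

    def test_matches_classical_formula_without_covariates(self, rng):
        Xtr, tr, Xte, te = self._split(rng)
        m = fit_glm(Xtr, tr)
        nullm = null_fit(tr)
        got = out_of_sample_r2(m, nullm, Xte, te)
        pred = predict(m, Xte, np.empty((len(te.y), 0)))
        expected = 1 - np.sum((te.y - pred) ** 2) / np.sum((te.y - tr.y.mean()) ** 2)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_overfit_logistic_model_scores_negative(self, rng):
        # p close to n_train on pure-noise features: honest R2 < 0
        n_train, n_test, p = 60, 300, 40
        Xtr = rng.standard_normal((n_train, p))
        Xte = rng.standard_normal((n_test, p))
        tr = PhenotypeTable((rng.random(n_train) < 0.5).astype(float), family="logistic")
        te = PhenotypeTable((rng.random(n_test) < 0.5).astype(float), family="logistic")
        m = fit_glm(Xtr, tr)
        nullm = null_fit(tr)
        assert out_of_sample_r2(m, nullm, Xte, te) < 0

    def test_invariant_to_affine_covariate_rescaling(self, rng):
        n = 300
        cov = rng.standard_normal((n, 1))
        X = rng.standard_normal((n, 1))
        y = X[:, 0] + 2 * cov[:, 0] + rng.standard_normal(n)
        half = n // 2
        r2 = []
        for scale, shift in [(1.0, 0.0), (37.0, -5.0)]:
            c = cov * scale + shift
            tr = PhenotypeTable(y[:half], c[:half], "linear")
            te = PhenotypeTable(y[half:], c[half:], "linear")
            m = fit_glm(X[:half], tr)
            r2.append(out_of_sample_r2(m, null_fit(tr), X[half:], te))
        assert r2[0] == pytest.approx(r2[1], rel=1e-8)

    def test_empty_test_fold_rejected(self, rng):
        tr = PhenotypeTable(rng.standard_normal(10), family="linear")
        m = null_fit(tr)
        with pytest.raises(ValueError):
            out_of_sample_r2(m, m, None, PhenotypeTable(np.empty(0), family="linear"))

    def test_in_sample_beats_out_of_sample_under_null(self, rng):
        # training-data evaluation is optimistic relative to held-out data
        diffs = []
        for _ in range(40):
            X = rng.standard_normal((80, 5))
            y = rng.standard_normal(80)
            tr = PhenotypeTable(y[:40], family="linear")
            te = PhenotypeTable(y[40:], family="linear")
            m = fit_glm(X[:40], tr)
            nullm = null_fit(tr)
            r2_in = out_of_sample_r2(m, nullm, X[:40], tr)
            r2_out = out_of_sample_r2(m, nullm, X[40:], te)
            diffs.append(r2_in - r2_out)
        assert np.mean(diffs) > 0
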