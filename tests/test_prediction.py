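"""Risk prediction: prevalence adjustment, AUC against pair counting,
risk categorization, reclassification tables and the categorical NRI."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from cgsreclass.prediction import (
    PrevalenceAdjustedLogit,
    adjust_intercept,
    auc,
    auc_ci,
    categorize_risk,
    fit_risk_models,
    nri,
    nri_from_tables,
    predicted_risk,
    reclassification_table,
)


class TestAdjustIntercept:
    def test_sample_prevalence_gives_zero_shift(self):
        assert adjust_intercept(0.7, 0.5, 1000, 1000) == pytest.approx(0.7)

    def test_study_numbers(self):
        assert adjust_intercept(0.0, 0.1, 2569, 5882) == pytest.approx(
            np.log(0.1 / 0.9 * 2569 / 5882)
        )
        assert adjust_intercept(0.0, 0.1, 2569, 5882) == pytest.approx(-3.026, abs=1e-3)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.1])
    def test_boundary_rho_rejected(self, rho):
        with pytest.raises(ValueError):
            adjust_intercept(0.0, rho, 10, 10)


class TestPrevalenceAdjustedLogit:
    def test_sklearn_api(self, rng):
        est = PrevalenceAdjustedLogit(prevalence=0.2)
        assert clone(est).get_params()["prevalence"] == 0.2
        X = rng.normal(0, 1, (100, 2))
        y = rng.binomial(1, 0.4, 100)
        est.fit(X, y)
        assert est.coef_.shape == (1, 2)
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert ((proba > 0) & (proba < 1)).all()

    def test_toy_inverse_logit(self):
        est = PrevalenceAdjustedLogit(prevalence=None)
        est.classes_ = np.array([0.0, 1.0])
        est.n_features_in_ = 1
        est.intercept_ = np.array([-3.0])
        est.coef_ = np.array([[1.0]])
        est.intercept_adjustment_ = 0.0
        assert predicted_risk(est, np.array([[3.0]]))[0] == pytest.approx(0.5)
        assert predicted_risk(est, np.array([[-30.0]]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_sample_case_fraction_matches_unadjusted(self, rng):
        X = rng.normal(0, 1, (200, 2))
        y = np.r_[np.ones(80), np.zeros(120)]
        raw = PrevalenceAdjustedLogit(prevalence=None).fit(X, y)
        adj = PrevalenceAdjustedLogit(prevalence=80 / 200).fit(X, y)
        np.testing.assert_allclose(
            raw.predict_proba(X)[:, 1], adj.predict_proba(X)[:, 1], atol=1e-12
        )

    def test_monotone_in_positive_coefficient(self, rng):
        X = rng.normal(0, 1, (300, 1))
        y = rng.binomial(1, 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        est = PrevalenceAdjustedLogit().fit(X, y)
        grid = np.linspace(-3, 3, 50).reshape(-1, 1)
        assert np.all(np.diff(est.predict_proba(grid)[:, 1]) > 0)

    def test_missing_covariates_rejected(self, rng):
        X = rng.normal(0, 1, (50, 2))
        X[3, 1] = np.nan
        y = np.r_[np.ones(25), np.zeros(25)]
        with pytest.raises(ValueError, match="missing"):
            PrevalenceAdjustedLogit().fit(X, y)


def pair_counting_auc(cases, controls):
    wins = ties = 0
    for a in cases:
        for b in controls:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestAuc:
    @pytest.mark.parametrize(
        "cases, controls, expected",
        [
            ([0.9, 0.8], [0.1, 0.2], 1.0),
            ([0.5, 0.5], [0.5, 0.5], 0.5),
            ([0.9, 0.4], [0.5, 0.1], 0.75),
        ],
    )
    def test_examples(self, cases, controls, expected):
        assert auc(cases, controls) == pytest.approx(expected)

    def test_matches_pair_counting(self, rng):
        for _ in range(10):
            a = rng.choice(np.linspace(0, 1, 11), size=15)  # forces ties
            b = rng.choice(np.linspace(0, 1, 11), size=12)
            assert auc(a, b) == pytest.approx(pair_counting_auc(a, b), abs=1e-12)

    def test_complement_symmetry_tie_free(self, rng):
        a = rng.normal(1, 1, 20)
        b = rng.normal(0, 1, 25)
        assert auc(a, b) + auc(-a, -b) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])

    def test_ci_contains_point_and_shrinks(self):
        lo1, hi1 = auc_ci(0.75, 100, 100)
        lo2, hi2 = auc_ci(0.75, 5000, 2500)
        assert lo1 < 0.75 < hi1
        assert hi2 - lo2 < hi1 - lo1


class TestCategorize:
    @pytest.mark.parametrize(
        "risk, cat",
        [(0.0, 1), (0.049, 1), (0.05, 2), (0.0999, 2), (0.10, 3),
         (0.15, 4), (0.1999, 4), (0.20, 5), (1.0, 5)],
    )
    def test_half_open_boundaries(self, risk, cat):
        assert categorize_risk(np.array([risk]))[0] == cat

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_risk(np.array([1.2]))


class TestReclassification:
    def test_identical_categories_diagonal(self):
        cats = np.array([1, 2, 3, 4, 5, 3])
        status = np.array([1, 1, 1, 0, 0, 0])
        res = reclassification_table(cats, cats, status)
        assert res.up_cases == res.down_cases == 0
        assert res.up_controls == res.down_controls == 0
        assert nri(res).nri == 0.0

    def test_three_subject_toy(self):
        res = reclassification_table(
            np.array([1, 2, 3]), np.array([2, 2, 1]), np.array([1, 1, 1])
        )
        assert res.up_cases == 1 and res.down_cases == 1

    def test_margins_conserved(self, rng):
        n = 200
        a = rng.integers(1, 6, n)
        b = rng.integers(1, 6, n)
        s = rng.integers(0, 2, n)
        res = reclassification_table(a, b, s)
        assert res.table_cases.to_numpy().sum() == (s == 1).sum()
        assert res.table_controls.to_numpy().sum() == (s == 0).sum()
        # row sums = baseline category counts among cases
        counts = pd.Series(a[s == 1]).value_counts().reindex(
            range(1, 6), fill_value=0
        )
        np.testing.assert_array_equal(res.table_cases.sum(axis=1), counts)

    def test_nri_invariant_to_subject_order(self, rng):
        n = 300
        a = rng.integers(1, 6, n)
        b = rng.integers(1, 6, n)
        s = rng.integers(0, 2, n)
        r1 = nri(reclassification_table(a, b, s))
        perm = rng.permutation(n)
        r2 = nri(reclassification_table(a[perm], b[perm], s[perm]))
        assert r1.nri == pytest.approx(r2.nri)
        assert r1.se == pytest.approx(r2.se)

    def test_nri_matches_signed_proportion_formula(self, rng):
        n = 500
        a = rng.integers(1, 6, n)
        b = rng.integers(1, 6, n)
        s = rng.integers(0, 2, n)
        res = nri(reclassification_table(a, b, s))
        expected = (res.up_cases - res.down_cases) / res.n_cases + (
            res.down_controls - res.up_controls
        ) / res.n_controls
        assert res.nri == pytest.approx(expected, abs=1e-15)
        assert -2.0 <= res.nri <= 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reclassification_table([1, 2], [1], [1, 0])


class TestFitRiskModels:
    def make_cohort(self, rng, n=1500, score_effect=0.25):
        n1 = n // 2
        y = np.r_[np.ones(n1), np.zeros(n - n1)]
        age = np.r_[rng.normal(57, 13, n1), rng.normal(45, 18, n - n1)]
        bmi = np.r_[rng.normal(25, 4, n1), rng.normal(22, 3.5, n - n1)]
        sex = rng.binomial(1, 0.46, n)
        score = rng.binomial(16, 0.45, n) + score_effect * y * rng.poisson(2, n)
        cov = pd.DataFrame({"sex": sex, "age": age, "bmi": bmi})
        return cov, score.astype(float), y

    def test_nested_log_likelihood(self, rng):
        cov, score, y = self.make_cohort(rng)
        fits = fit_risk_models(cov, score, y)
        assert fits["clinical_plus_cgs"].llf >= fits["clinical"].llf - 1e-8

    def test_informative_score_discriminates(self, rng):
        cov, score, y = self.make_cohort(rng, score_effect=1.0)
        fits = fit_risk_models(cov, score, y)
        assert fits["cgs_only"].auc > 0.55

    def test_null_score_adds_no_auc(self, rng):
        cov, score, y = self.make_cohort(rng, n=6000, score_effect=0.0)
        fits = fit_risk_models(cov, score, y)
        assert abs(fits["clinical_plus_cgs"].auc - fits["clinical"].auc) < 0.01

    def test_shared_prevalence_adjustment(self, rng):
        cov, score, y = self.make_cohort(rng)
        fits = fit_risk_models(cov, score, y, prevalence=0.10)
        adjustments = {f.model.intercept_adjustment_ for f in fits.values()}
        assert len(adjustments) == 1


def test_nri_from_tables_validates_shape():
    with pytest.raises(ValueError):
        nri_from_tables(np.zeros((5, 5)), np.zeros((4, 4)))
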