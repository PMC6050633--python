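import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from balancesel import (
    criterion_auc,
    criterion_pseudo_r2,
    criterion_tjur,
    fit_linear,
    fit_logistic,
)
from balancesel.models import CollinearityError


def brute_force_auc(scores, y):
    """P(score_pos > score_neg) + 0.5 P(tie) by explicit pair enumeration."""
    pos = [s for s, yi in zip(scores, y) if yi == 1]
    neg = [s for s, yi in zip(scores, y) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize(
        "probs, y, expected",
        [
            ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
            # pairs: 0.9>0.5, 0.9>0.1, 0.4<0.5, 0.4>0.1 -> 3/4
            ([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_worked_examples(self, probs, y, expected):
        assert criterion_auc(np.array(probs), np.array(y)) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            criterion_auc(np.array([0.1, 0.9]), np.array([1.0, 1.0]))

    @settings(max_examples=100, deadline=None)
    @given(
        scores=st.lists(st.integers(0, 5), min_size=2, max_size=50),
        data=st.data(),
    )
    def test_matches_pairwise_enumeration(self, scores, data):
        """Mann-Whitney midrank form equals the O(n^2) pair count, ties and all."""
        n = len(scores)
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < n
            )
        )
        scores = np.array(scores, dtype=float)
        y = np.array(y, dtype=float)
        assert criterion_auc(scores, y) == pytest.approx(
            brute_force_auc(scores, y), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=80)
        y = rng.integers(0, 2, 80).astype(float)
        assert criterion_auc(scores, y) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )


class TestFitLinear:
    def test_exact_fit_recovers_slope(self, rng):
        scores = rng.normal(size=30)
        y = 1.5 + 2.0 * scores
        fit = fit_linear(scores, y)
        assert fit.criterion_value == pytest.approx(0.0, abs=1e-16)
        assert fit.beta1 == pytest.approx(2.0, abs=1e-8)

    def test_null_mse_matches_ols_theory(self):
        """E[mean squared residual] = sigma^2 (n-p)/n for pure-noise y."""
        rng = np.random.default_rng(5)
        n, reps = 100, 1000
        mses = []
        for _ in range(reps):
            scores = rng.normal(size=n)
            y = rng.normal(size=n)
            mses.append(fit_linear(scores, y).criterion_value)
        assert np.mean(mses) == pytest.approx((n - 2) / n, abs=0.02)

    def test_covariate_absorbs_confound(self, rng):
        z = rng.normal(size=50)
        scores = rng.normal(size=50)
        y = 3.0 * z
        fit = fit_linear(scores, y, z)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.criterion_value == pytest.approx(0.0, abs=1e-16)

    def test_collinear_design_names_columns(self, rng):
        scores = rng.normal(size=30)
        z = np.column_stack([scores, rng.normal(size=30)])  # z0 duplicates balance
        with pytest.raises(CollinearityError, match="collinear"):
            fit_linear(scores, 2 * scores, z)

    def test_matches_statsmodels_ols(self, rng):
        scores = rng.normal(size=60)
        z = rng.normal(size=(60, 2))
        y = 0.5 + scores - z[:, 0] + rng.normal(size=60)
        fit = fit_linear(scores, y, z)
        ref = sm.OLS(y, sm.add_constant(np.column_stack([scores, z]))).fit()
        np.testing.assert_allclose(
            [fit.beta0, fit.beta1, *fit.gamma], ref.params, rtol=1e-8
        )
        assert fit.criterion_value == pytest.approx(
            np.mean(ref.resid**2), rel=1e-10
        )


class TestFitLogistic:
    def test_matches_statsmodels_logit(self, rng):
        scores = rng.normal(size=120)
        z = rng.normal(size=120)
        eta = 0.3 + 0.8 * scores - 0.5 * z
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(scores, y, z)
        ref = sm.Logit(y, sm.add_constant(np.column_stack([scores, z]))).fit(disp=0)
        assert fit.converged
        np.testing.assert_allclose(
            [fit.beta0, fit.beta1, *fit.gamma], ref.params, rtol=1e-6, atol=1e-8
        )
        assert fit.loglik == pytest.approx(ref.llf, rel=1e-9)

    def test_separation_falls_back_to_ridge(self):
        scores = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = np.array([0.0, 0, 0, 1, 1, 1])
        fit = fit_logistic(scores, y)
        assert not fit.converged
        assert np.isfinite(fit.beta1) and fit.beta1 > 0
        assert fit.criterion_value == pytest.approx(1.0)

    def test_null_training_auc_matches_folded_normal_oracle(self):
        """For y independent of the scores, the fitted model's training AUC is
        max(A, 1-A) with A the raw-score AUC, whose null mean is
        0.5 + sd * sqrt(2/pi), sd^2 = (n+1)/(12 n1 n0); beta1 averages 0."""
        rng = np.random.default_rng(11)
        n = 200
        aucs, slopes = [], []
        for _ in range(1000):
            scores = rng.normal(size=n)
            y = np.repeat([0.0, 1.0], n // 2)
            fit = fit_logistic(scores, y)
            aucs.append(fit.criterion_value)
            slopes.append(fit.beta1)
        sd = np.sqrt((n + 1) / (12 * (n / 2) ** 2))
        expected = 0.5 + sd * np.sqrt(2 / np.pi)
        assert np.mean(aucs) == pytest.approx(expected, abs=0.01)
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.02)

    def test_label_flip_flips_slope_not_criterion(self, rng):
        scores = rng.normal(size=100)
        y = rng.binomial(1, 1 / (1 + np.exp(-scores))).astype(float)
        a = fit_logistic(scores, y)
        b = fit_logistic(scores, 1.0 - y)
        assert b.beta1 == pytest.approx(-a.beta1, rel=1e-5)
        # AUC after re-orienting the balance (score sign flip) is unchanged
        assert b.criterion_value == pytest.approx(a.criterion_value, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.r_[0.1, 0.2, 0.3], np.ones(3))

    def test_affine_rescaled_scores_give_identical_criterion(self, rng):
        scores = rng.normal(size=100)
        y = rng.binomial(1, 1 / (1 + np.exp(-scores))).astype(float)
        a = fit_logistic(scores, y)
        b = fit_logistic(3.0 * scores + 5.0, y)
        assert b.criterion_value == pytest.approx(a.criterion_value, abs=1e-9)
        assert b.beta1 == pytest.approx(a.beta1 / 3.0, rel=1e-5)


class TestSecondaryCriteria:
    def test_tjur_perfect_and_constant(self):
        y = np.array([1.0, 1, 0, 0])
        assert criterion_tjur(np.array([1.0, 1, 0, 0]), y) == 1.0
        assert criterion_tjur(np.full(4, 0.3), y) == 0.0

    def test_pseudo_r2_null_is_zero(self):
        assert criterion_pseudo_r2(-10.0, -10.0) == 0.0

    def test_pseudo_r2_zero_null_loglik_rejected(self):
        with pytest.raises(ValueError):
            criterion_pseudo_r2(-1.0, 0.0)

    def test_criteria_selectable_in_fit(self, rng):
        scores = rng.normal(size=100)
        y = rng.binomial(1, 1 / (1 + np.exp(-2 * scores))).astype(float)
        f_tjur = fit_logistic(scores, y, criterion="tjur_d")
        f_r2 = fit_logistic(scores, y, criterion="pseudo_r2")
        assert 0 < f_tjur.criterion_value <= 1
        assert 0 < f_r2.criterion_value <= 1
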