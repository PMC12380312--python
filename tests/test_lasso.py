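"""Lasso-logistic fitting, CV ensembles, AUC, median-nonzero selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from mskprisk.lasso import (CvPlan, OrDistribution, auc, cross_validate,
                            fit_lasso_logistic, select_by_median)


def _newton_raphson_logistic(X, y, tol=1e-12, max_iter=100):
    """Independent unpenalized-MLE oracle (pure Newton iterations)."""
    Z = np.column_stack([np.ones(len(X)), X])
    b = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        p = expit(Z @ b)
        g = Z.T @ (y - p)
        H = Z.T @ (Z * (p * (1 - p))[:, None])
        step = np.linalg.solve(H, g)
        b += step
        if np.abs(step).max() < tol:
            break
    return b


def _pair_counting_auc(y, s):
    """Brute-force AUC: fraction of (pos, neg) pairs ranked correctly,
    ties counting one half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(7)
    n = 2000
    X = pd.DataFrame(rng.standard_normal((n, 6)),
                     columns=[f"x{i}" for i in range(6)])
    eta = -1.3 + 1.0 * X["x0"].to_numpy() - 0.5 * X["x1"].to_numpy()
    y = (rng.random(n) < expit(eta)).astype(int)
    return X, y


class TestFitLassoLogistic:
    def test_full_shrinkage_limit(self, toy_data):
        X, y = toy_data
        m = fit_lasso_logistic(X, y, 1e6)
        assert (m.coef == 0).all()
        assert m.intercept == pytest.approx(float(logit(y.mean())), abs=5e-3)

    def test_unpenalized_matches_newton_oracle(self, toy_data):
        X, y = toy_data
        m = fit_lasso_logistic(X, y, 0.0)
        oracle = _newton_raphson_logistic(X.to_numpy(), y)
        fitted = np.r_[m.intercept, m.coef.to_numpy()]
        assert np.abs(fitted - oracle).max() < 1e-4

    def test_strong_predictor_selected_noise_zeroed(self):
        """With one true per-SD log-odds of 1.0 at n=2000 and a moderate
        penalty, the true predictor is always kept and pure-noise
        coefficients are mostly exact zeros (50 replicates)."""
        strong_kept = 0
        noise_zeroed = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            X = pd.DataFrame(rng.standard_normal((2000, 6)),
                             columns=[f"x{i}" for i in range(6)])
            y = (rng.random(2000) < expit(-1.3 + X["x0"].to_numpy())).astype(int)
            m = fit_lasso_logistic(X, y, 40.0)
            strong_kept += m.coef["x0"] != 0
            noise = m.coef.drop("x0")
            noise_zeroed.append((noise == 0).mean())
        assert strong_kept == 50
        assert np.mean(noise_zeroed) >= 0.8

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="single class"):
            fit_lasso_logistic(X, np.ones(3, dtype=int), 1.0)

    def test_negative_lambda_rejected(self, toy_data):
        X, y = toy_data
        with pytest.raises(ValueError):
            fit_lasso_logistic(X, y, -1.0)

    def test_shrinkage_monotone_in_lambda(self, toy_data):
        X, y = toy_data
        nonzero = [int((fit_lasso_logistic(X, y, lam).coef != 0).sum())
                   for lam in (0.1, 1.0, 10.0, 100.0, 1000.0)]
        assert nonzero == sorted(nonzero, reverse=True)


class TestCrossValidate:
    def test_single_grid_value_and_member_count(self, toy_data):
        X, y = toy_data
        plan = CvPlan(n_repeats=20, n_folds=3, seed=3)
        res = cross_validate(X.iloc[:600], y[:600], plan, [5.0])
        assert res.best_lambda == 5.0
        assert len(res.ensemble.members) == 60
        assert plan.n_models == 60
        assert len(res.ensemble.test_aucs) == 60

    def test_pure_noise_auc_at_chance(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.standard_normal((300, 8)),
                         columns=[f"n{i}" for i in range(8)])
        y = rng.integers(0, 2, 300)
        res = cross_validate(X, y, CvPlan(seed=4), [10.0])
        assert res.mean_auc == pytest.approx(0.5, abs=0.05)

    def test_stratified_folds_preserve_prevalence(self, toy_data):
        X, y = toy_data
        plan = CvPlan(seed=5)
        prev = y.mean()
        for train_idx, test_idx in plan.splits(X, y):
            for part in (train_idx, test_idx):
                assert abs(y[part].sum() - prev * len(part)) <= 1.0

    def test_deterministic_under_seed(self, toy_data):
        X, y = toy_data
        Xs, ys = X.iloc[:400], y[:400]
        r1 = cross_validate(Xs, ys, CvPlan(n_repeats=3, seed=9), [2.0])
        r2 = cross_validate(Xs, ys, CvPlan(n_repeats=3, seed=9), [2.0])
        pd.testing.assert_frame_equal(r1.ensemble.coef_matrix,
                                      r2.ensemble.coef_matrix)
        assert r1.ensemble.test_aucs == r2.ensemble.test_aucs

    def test_single_class_fold_refused(self):
        X = pd.DataFrame({"x": np.arange(12.0)})
        y = np.array([1] + [0] * 11)  # one positive cannot stratify 3 folds
        with pytest.raises(ValueError):
            cross_validate(X, y, CvPlan(seed=0), [1.0])

    def test_grid_tie_prefers_larger_lambda(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((90, 2)), columns=["a", "b"])
        y = rng.integers(0, 2, 90)
        res = cross_validate(X, y, CvPlan(n_repeats=2, seed=0), [1e5, 1e6])
        # both lambdas shrink everything: identical chance AUCs, tie -> larger
        assert res.best_lambda == 1e6


class TestSelectByMedian:
    def _dist(self, coefs: dict) -> OrDistribution:
        return OrDistribution(per_fold=np.exp(pd.DataFrame(coefs)))

    def test_zeroed_in_majority_dropped(self):
        coefs = {"mostly_zero": [0.0] * 31 + [0.5] * 29,
                 "always_on": [0.3] * 60}
        assert select_by_median(self._dist(coefs)) == ["always_on"]

    def test_all_zero_feature_has_unit_or(self):
        dist = self._dist({"dead": [0.0] * 60})
        assert (dist.per_fold["dead"] == 1.0).all()
        assert select_by_median(dist) == []


class TestAuc:
    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for n in (10, 57, 200):
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = rng.choice(np.linspace(0, 1, 11), size=n)  # force ties
            assert auc(y, s) == pytest.approx(_pair_counting_auc(y, s),
                                              abs=1e-12)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
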