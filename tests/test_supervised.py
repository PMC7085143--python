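"""Supervised learners against independent second-order oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from lifelines import CoxPHFitter

import txbench as tb
from txbench.supervised import DEPTH_GRID, KNN_GRID, PENALTY_GRID


def test_benchmark_grids_match_design():
    np.testing.assert_allclose(PENALTY_GRID, np.logspace(-6, 3, 10))
    assert DEPTH_GRID == (2, 4, 8, 16, 32, 64, 128)
    assert KNN_GRID == (1, 3, 5, 7, 9)


class TestLogistic:
    def test_separable_toy_is_memorized(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        m = tb.fit_logistic(X, y, 1e-6, max_iter=5000)
        assert tb.accuracy(m.predict_class(X), y) == 1.0

    def test_heavy_penalty_crushes_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 4))
        y = (X[:, 0] > 0).astype(int)
        small = tb.fit_logistic(X, y, 1e-6, max_iter=5000)
        large = tb.fit_logistic(X, y, 1e3, max_iter=5000)
        assert np.linalg.norm(large.coefficients) < 0.01 * np.linalg.norm(
            small.coefficients
        )

    def test_matches_newton_oracle(self):
        """Unpenalized binary fit agrees with statsmodels' Newton solver.

        The softmax parameterization is only identified up to a shift, so
        the comparison is on class-coefficient differences."""
        rng = np.random.default_rng(3)
        n, p = 200, 5
        X = rng.normal(size=(n, p))
        beta = np.array([1.0, -0.5, 0.3, 0.0, 0.8])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-(X @ beta + 0.2)))).astype(int)
        m = tb.fit_logistic(X, y, 0.0, max_iter=50000, tol=1e-10)
        ours = np.r_[
            m.intercept[1] - m.intercept[0], m.coefficients[1] - m.coefficients[0]
        ]
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        assert np.abs(ours - ref).max() < 1e-2

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(90, 3))
        y = rng.integers(3, size=90)
        m = tb.fit_logistic(X, y, 0.01, max_iter=500)
        np.testing.assert_allclose(m.predict_proba(X).sum(axis=1), 1.0, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two observed classes"):
            tb.fit_logistic(np.ones((5, 2)), np.zeros(5), 0.1)


class TestForestAndKNN:
    def _toy(self, n=50):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(n, 3))
        y = (X[:, 0] + 0.2 * rng.normal(size=n) > 0).astype(int)
        return X, y

    def test_deep_forest_overfits_training_data(self):
        X, y = self._toy()
        m = tb.fit_rf(X, y, 128, seed=0)
        assert tb.accuracy(m.predict_class(X), y) >= 0.98

    def test_one_nearest_neighbor_memorizes(self):
        X, y = self._toy()
        m = tb.fit_knn(X, y, 1)
        assert tb.accuracy(m.predict_class(X), y) == 1.0

    def test_k_equals_n_votes_majority(self):
        X, y = self._toy()
        y[:40] = 1  # strong imbalance
        m = tb.fit_knn(X, y, len(X))
        assert (m.predict_class(X) == 1).all()

    def test_k_beyond_n_rejected(self):
        X, y = self._toy(10)
        with pytest.raises(ValueError, match="exceeds"):
            tb.fit_knn(X, y, 11)


def _brute_force_partial_likelihood(beta, X, times, events):
    """Standard (no-ties) Cox partial likelihood by direct enumeration."""
    eta = X @ beta
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return -ll


class TestEfronPseudolikelihood:
    def test_two_subject_toy(self):
        """One event among two at-risk subjects at beta=0: uniform risk."""
        negll, _ = tb.efron_pseudolikelihood(
            np.zeros(1), np.zeros((2, 1)), np.array([1.0, 2.0]), np.array([1, 0])
        )
        assert negll == pytest.approx(np.log(2))

    def test_tied_pair_toy_hand_computed(self):
        """Three subjects, two tied events at t=1, one censored later, beta=0:
        Efron denominators 3 and 3 - (1/2)*2 = 2, so -loglik = log 6."""
        negll, _ = tb.efron_pseudolikelihood(
            np.zeros(1), np.zeros((3, 1)), np.array([1.0, 1.0, 2.0]), np.array([1, 1, 0])
        )
        assert negll == pytest.approx(np.log(6), abs=1e-12)

    def test_tie_free_equals_standard_partial_likelihood(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n, p = 40, 3
            X = rng.normal(size=(n, p))
            times = rng.exponential(size=n)  # continuous: tie-free
            events = (rng.uniform(size=n) < 0.7).astype(int)
            events[0] = 1
            beta = rng.normal(size=p) * 0.5
            ours, _ = tb.efron_pseudolikelihood(beta, X, times, events)
            ref = _brute_force_partial_likelihood(beta, X, times, events)
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(6)
        for trial in range(3):
            n, p = 30, 4
            X = rng.normal(size=(n, p))
            times = np.round(rng.exponential(size=n), 1) + 0.1  # forces ties
            events = (rng.uniform(size=n) < 0.6).astype(int)
            events[0] = 1
            beta = rng.normal(size=p) * 0.3
            _, grad = tb.efron_pseudolikelihood(beta, X, times, events)
            h = 1e-5
            for j in range(p):
                e = np.eye(p)[j] * h
                fp, _ = tb.efron_pseudolikelihood(beta + e, X, times, events)
                fm, _ = tb.efron_pseudolikelihood(beta - e, X, times, events)
                assert grad[j] == pytest.approx((fp - fm) / (2 * h), abs=1e-5)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="at least one event"):
            tb.efron_pseudolikelihood(
                np.zeros(1), np.zeros((3, 1)), np.arange(1.0, 4.0), np.zeros(3, int)
            )


class TestCoxFit:
    def _data(self, n=50, p=3, seed=7):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.array([0.8, -0.5, 0.3])[:p]
        times = rng.exponential(size=n) / np.exp(X @ beta)
        events = (rng.uniform(size=n) < 0.7).astype(int)
        events[0] = 1
        return X, times, events

    def test_matches_newton_oracle(self):
        X, times, events = self._data()
        m = tb.fit_cox_efron(X, times, events, 0.0, max_iter=50000, tol=1e-10)
        df = pd.DataFrame(np.c_[X, times, events], columns=["a", "b", "c", "T", "E"])
        ref = CoxPHFitter(penalizer=0).fit(df, "T", "E").params_.values
        assert np.abs(m.coefficients - ref).max() < 1e-2

    def test_heavy_penalty_shrinks_to_zero(self):
        X, times, events = self._data()
        m = tb.fit_cox_efron(X, times, events, 1e3, max_iter=2000)
        assert np.linalg.norm(m.coefficients) < 1e-3

    def test_subject_order_invariance(self):
        X, times, events = self._data()
        m1 = tb.fit_cox_efron(X, times, events, 0.01, max_iter=1000)
        perm = np.random.default_rng(0).permutation(len(X))
        m2 = tb.fit_cox_efron(X[perm], times[perm], events[perm], 0.01, max_iter=1000)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-10)


class TestSingleGene:
    def test_inner_loop_finds_the_informative_gene(self):
        """Only gene 1 of 3 separates the classes: every outer fold's inner
        search must select it."""
        rng = np.random.default_rng(8)
        n = 100
        y = rng.integers(2, size=n)
        X = rng.normal(size=(n, 3))
        X[:, 1] += 3.0 * y
        task = tb.TaskSpec("toy", "binary", "train",
                           np.array([f"s{i}" for i in range(n)]), labels=y)
        learner = tb.SingleGeneLearner(3, "classification", max_iter=200)
        res = tb.nested_cv_run(task, X, learner, tb.make_folds(task, 5, 0), seed=0)
        assert res.fold_hyperparameters == [1] * 5
        assert res.mean_metric > 0.95

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        a = tb.fit_single_gene_logistic(X, y, 0, seed=1)
        b = tb.fit_single_gene_logistic(X, y, 0, seed=1)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
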