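"""LSPC, model selection, metrics, permutation and Wilcoxon tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import chirpdecode as cd
from chirpdecode.classify import (
    _stratified_folds, DEFAULT_LAMBDAS, WilcoxonResult,
)


def make_blobs(n_per_class, dim=4, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    mu = np.zeros(dim)
    mu[0] = sep
    Xa = rng.normal(size=(n_per_class, dim))
    Xb = rng.normal(size=(n_per_class, dim)) + mu
    X = np.vstack([Xa, Xb])
    y = np.array(["chirp"] * n_per_class + ["silent"] * n_per_class)
    return X, y


class TestLspc:
    def test_two_point_interpolation_limit(self):
        X = np.array([[0.0], [10.0]])
        y = np.array(["chirp", "silent"])
        model = cd.lspc_fit(X, y, sigma=1.0, lam=1e-6)
        _, post = cd.lspc_predict(model, X)
        assert post[0, 0] > 0.99 and post[1, 1] > 0.99

    def test_theta_matches_dense_normal_equations(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        y = np.array(["chirp", "silent"] * 3)
        sigma, lam = 1.3, 0.1
        model = cd.lspc_fit(X, y, sigma, lam)
        # independent dense solve
        D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        G = np.exp(-D2 / (2 * sigma**2))
        B = np.column_stack([(y == "chirp").astype(float),
                             (y == "silent").astype(float)])
        theta = np.linalg.solve(G.T @ G / 6 + lam * np.eye(6), G.T @ B / 6)
        assert np.abs(theta - model.theta).max() < 1e-8

    def test_duplicating_training_points_leaves_predictions_unchanged(self):
        X, y = make_blobs(10, seed=1)
        m1 = cd.lspc_fit(X, y, sigma=2.0, lam=0.1)
        m2 = cd.lspc_fit(np.vstack([X, X]), np.concatenate([y, y]),
                         sigma=2.0, lam=0.1)
        Xq = np.random.default_rng(2).normal(size=(50, 4))
        p1, _ = cd.lspc_predict(m1, Xq)
        p2, _ = cd.lspc_predict(m2, Xq)
        assert np.array_equal(p1, p2)

    def test_posteriors_normalized(self):
        X, y = make_blobs(20, seed=3)
        model = cd.lspc_fit(X, y, sigma=2.0, lam=0.1)
        _, post = cd.lspc_predict(
            model, np.random.default_rng(4).normal(size=(40, 4)))
        assert np.all(post >= 0) and np.all(post <= 1)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_training_points_classified_by_interpolating_model(self):
        X, y = make_blobs(10, seed=5)
        model = cd.lspc_fit(X, y, sigma=0.5, lam=1e-8)
        pred, _ = cd.lspc_predict(model, X)
        assert np.array_equal(pred, y)

    def test_separable_blobs_generalize(self):
        Xtr, ytr = make_blobs(100, seed=6)
        Xte, yte = make_blobs(100, seed=7)
        model = cd.lspc_fit(Xtr, ytr, sigma=2.0, lam=0.01)
        pred, _ = cd.lspc_predict(model, Xte)
        assert np.mean(pred == yte) > 0.95

    def test_label_permutation_equivariance(self):
        X, y = make_blobs(15, seed=8)
        swapped = np.where(y == "chirp", "silent", "chirp")
        m1 = cd.lspc_fit(X, y, sigma=2.0, lam=0.1)
        m2 = cd.lspc_fit(X, swapped, sigma=2.0, lam=0.1)
        np.testing.assert_allclose(m1.theta, m2.theta[:, ::-1], atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        X, y = make_blobs(5, seed=9)
        model = cd.lspc_fit(X, y, sigma=1.0, lam=0.1)
        with pytest.raises(ValueError, match="dimension"):
            cd.lspc_predict(model, np.zeros((3, 7)))


class TestInnerCv:
    def test_protocol_fold_sizes(self):
        y = np.array(["chirp"] * 150 + ["silent"] * 150)
        fold = _stratified_folds(y, 10, np.random.default_rng(0))
        for f in range(10):
            va = fold == f
            assert (y[va] == "chirp").sum() == 15
            assert (y[va] == "silent").sum() == 15
            assert (y[~va] == "chirp").sum() == 135
            assert (y[~va] == "silent").sum() == 135

    def test_single_point_grid_returned(self):
        X, y = make_blobs(20, seed=0)
        s, l, _ = cd.inner_cv_select(X, y, n_folds=5, sigma_grid=[2.0],
                                     lambda_grid=[0.1], seed=0)
        assert s == 2.0 and l == 0.1

    def test_fixed_seed_reproducible(self):
        X, y = make_blobs(20, seed=1)
        r1 = cd.inner_cv_select(X, y, n_folds=5, seed=7)
        r2 = cd.inner_cv_select(X, y, n_folds=5, seed=7)
        assert r1[:2] == r2[:2]
        np.testing.assert_array_equal(r1[2].theta, r2[2].theta)

    def test_tie_break_prefers_small_sigma_then_large_lambda(self):
        # all grid points are equally perfect on fully separable data
        X, y = make_blobs(20, sep=50.0, seed=2)
        s, l, _ = cd.inner_cv_select(X, y, n_folds=5,
                                     sigma_grid=[3.0, 6.0],
                                     lambda_grid=[1e-3, 1e-2], seed=0)
        assert s == 3.0 and l == 1e-2


class TestEvaluateRepeated:
    def test_single_repeat_matches_manual_pipeline(self):
        Xtr, ytr = make_blobs(20, seed=0)
        Xte, yte = make_blobs(20, seed=1)
        rep = cd.evaluate_repeated(Xtr, ytr, Xte, yte, n_repeats=1, seed=3,
                                   n_folds=5)
        assert len(rep.metrics) == 1
        rng = np.random.default_rng(np.random.SeedSequence(3).spawn(1)[0])
        _, _, model = cd.inner_cv_select(Xtr, ytr, n_folds=5, rng=rng)
        pred, _ = cd.lspc_predict(model, Xte)
        manual = cd.compute_metrics(pred, yte)
        assert rep.metrics[0].accuracy == manual.accuracy

    def test_standard_error_definition(self):
        Xtr, ytr = make_blobs(15, sep=1.0, seed=4)
        Xte, yte = make_blobs(15, sep=1.0, seed=5)
        rep = cd.evaluate_repeated(Xtr, ytr, Xte, yte, n_repeats=8, seed=0,
                                   n_folds=5)
        accs = np.array([m.accuracy for m in rep.metrics])
        assert rep.se("accuracy") == pytest.approx(
            accs.std(ddof=1) / np.sqrt(len(accs)))

    def test_high_separation_reaches_high_accuracy(self):
        Xtr, ytr = make_blobs(50, sep=6.0, seed=6)
        Xte, yte = make_blobs(50, sep=6.0, seed=7)
        rep = cd.evaluate_repeated(Xtr, ytr, Xte, yte, n_repeats=3, seed=1,
                                   n_folds=5)
        assert rep.mean("accuracy") > 0.9


class TestMetrics:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_balanced_identity_holds_exactly(self, seed, n):
        rng = np.random.default_rng(seed)
        truth = np.array(["chirp"] * n + ["silent"] * n)
        pred = rng.choice(["chirp", "silent"], size=2 * n)
        m = cd.compute_metrics(pred, truth)
        identity = 1.0 - (m.false_positive_rate + m.false_negative_rate) / 2.0
        assert m.accuracy == pytest.approx(identity, abs=1e-12)

    def test_dprime_zero_at_chance(self):
        truth = np.array(["chirp"] * 10 + ["silent"] * 10)
        pred = np.array((["chirp"] * 5 + ["silent"] * 5) * 2)
        assert cd.compute_metrics(pred, truth).dprime == pytest.approx(0.0)

    def test_dprime_worked_value(self):
        # hit 0.8, false alarm 0.2 -> d' = 2 * z(0.8)
        truth = np.array(["chirp"] * 10 + ["silent"] * 10)
        pred = np.array(["chirp"] * 8 + ["silent"] * 2
                        + ["chirp"] * 2 + ["silent"] * 8)
        m = cd.compute_metrics(pred, truth)
        assert m.dprime == pytest.approx(2 * stats.norm.ppf(0.8), abs=1e-9)
        assert m.dprime == pytest.approx(1.683, abs=5e-4)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cd.compute_metrics(np.array(["chirp"]), np.array(["chirp"]))


class TestPermutationTest:
    def test_minimal_attainable_p_when_observed_beats_every_null(self):
        Xtr, ytr = make_blobs(20, sep=8.0, seed=0)
        Xte, yte = make_blobs(20, sep=8.0, seed=1)
        res = cd.permutation_test(Xtr, ytr, Xte, yte, n_perm=100, seed=0,
                                  observed_accuracy=1.01, n_folds=5,
                                  sigma_grid=[3.0], lambda_grid=[0.1])
        assert res.p_value == pytest.approx(1 / 101)

    def test_maximal_p_when_observed_below_null(self):
        Xtr, ytr = make_blobs(15, sep=0.2, seed=2)
        Xte, yte = make_blobs(15, sep=0.2, seed=3)
        res = cd.permutation_test(Xtr, ytr, Xte, yte, n_perm=20, seed=0,
                                  observed_accuracy=0.0, n_folds=5,
                                  sigma_grid=[2.0], lambda_grid=[0.1])
        assert res.p_value == 1.0

    def test_null_data_rarely_significant(self):
        fails = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Xtr = rng.normal(size=(40, 5))
            ytr = np.array(["chirp", "silent"] * 20)
            Xte = rng.normal(size=(20, 5))
            yte = np.array(["chirp", "silent"] * 10)
            res = cd.permutation_test(
                Xtr, ytr, Xte, yte, n_perm=19, seed=seed,
                n_observed_repeats=2, n_folds=5,
                sigma_grid=[3.0], lambda_grid=[0.1])
            fails += res.p_value <= 0.05
        assert fails <= 5  # p > 0.05 in >= 90 % of null runs


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        a = np.arange(8.0)
        with pytest.warns(UserWarning, match="zero"):
            res = cd.compare_conditions(a, a)
        assert res.p_value == 1.0

    def test_all_positive_distinct_n10(self):
        res = cd.compare_conditions(np.arange(1.0, 11.0), np.zeros(10))
        assert res.p_value == pytest.approx(2 / 1024)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 12))
        assert cd.compare_conditions(a, b).p_value == \
            cd.compare_conditions(b, a).p_value

    def test_exact_p_matches_full_enumeration_at_n10(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=10)
        res = cd.compare_conditions(d, np.zeros(10))
        # brute-force oracle over all 2^10 sign assignments
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array([np.sum(ranks[np.array(s)]) if any(s) else 0.0
                       for s in itertools.product([False, True], repeat=10)])
        cdf = np.mean(ws <= w_obs + 1e-12)
        sf = np.mean(ws >= w_obs - 1e-12)
        expected = min(1.0, 2 * min(cdf, sf))
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b = rng.normal(size=(2, 14))
            ours = cd.compare_conditions(a, b).p_value
            ref = stats.wilcoxon(a, b, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 40))
        ours = cd.compare_conditions(a, b).p_value
        ref = stats.wilcoxon(a, b, correction=True, mode="approx").pvalue
        assert ours == pytest.approx(ref, abs=0.02)

    def test_planted_five_point_effect_detected(self):
        # paired accuracies differing by 5 points with small jitter
        rng = np.random.default_rng(4)
        base = 0.70 + rng.normal(0.0, 0.01, size=10)
        res = cd.compare_conditions(base + 0.05, base)
        assert res.p_value < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="5"):
            cd.compare_conditions([1.0, 2.0], [0.0, 0.0])
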