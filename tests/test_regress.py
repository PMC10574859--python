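import numpy as np
import pytest

from wmeeg.fcm import FCMModel
from wmeeg.regress import (
    SVRModel,
    filter_clustering_set,
    kernel_matrix,
    kfsvr_fit,
    kfsvr_predict,
    lasso_fit,
    lasso_predict,
    mlsvr_fit,
    mlsvr_predict,
    svr_dual_objective,
    svr_fit,
    svr_predict,
    tune_svr,
)
from wmeeg.synth import SynthConfig, features_matrix, generate_dataset, labels_vector


class TestSVR:
    def test_linear_data_fits_inside_tube(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.3
        model = svr_fit(X, y, kernel="linear", C=100.0, epsilon=0.1)
        # within the tube up to solver tolerance
        assert np.abs(svr_predict(model, X) - y).max() <= 0.1 + 1e-3

    def test_single_training_point(self):
        model = svr_fit(np.array([[1.0, 2.0]]), np.array([0.7]))
        assert abs(svr_predict(model, np.array([1.0, 2.0])) - 0.7) <= model.epsilon

    def test_points_inside_tube_have_zero_dual_coefficient(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = X[:, 0] + 0.01 * rng.normal(size=30)
        model = svr_fit(X, y, kernel="linear", C=10.0, epsilon=0.2)
        # points strictly inside the tube must not appear as support vectors
        all_pred = svr_predict(model, X)
        inside = np.abs(all_pred - y) < 0.2 - 1e-2  # clearly inside the tube
        sv_set = {tuple(v) for v in model.support_vectors}
        for i in np.flatnonzero(inside):
            assert tuple(X[i]) not in sv_set

    def test_dual_coefficients_respect_box(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        model = svr_fit(X, y, kernel="gaussian", C=2.5)
        assert np.abs(model.dual_coefs).max() <= 2.5 + 1e-8

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            svr_fit(np.array([[np.inf]]), np.array([1.0]))

    def test_dual_objective_matches_constrained_optimizer(self):
        from scipy.optimize import minimize

        rng = np.random.default_rng(3)
        n, C, eps = 14, 2.0, 0.1
        X = rng.normal(size=(n, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=n)
        model = svr_fit(X, y, kernel="gaussian", C=C, epsilon=eps, gamma=0.5)
        K = kernel_matrix(X, X, "gaussian", 0.5)
        # my solution's dual objective
        beta_mine = np.zeros(n)
        for coef, sv in zip(model.dual_coefs, model.support_vectors):
            i = int(np.argmin(np.linalg.norm(X - sv, axis=1)))
            beta_mine[i] = coef
        obj_mine = svr_dual_objective(K, y, beta_mine, eps)

        # oracle: maximize the dual via SLSQP on the (p, q) split
        def neg_obj(pq):
            beta = pq[:n] - pq[n:]
            return -(-0.5 * beta @ K @ beta - eps * pq.sum() + y @ beta)

        res = minimize(
            neg_obj,
            np.zeros(2 * n),
            bounds=[(0, C)] * 2 * n,
            constraints={"type": "eq", "fun": lambda pq: pq[:n].sum() - pq[n:].sum()},
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        assert abs(obj_mine - (-res.fun)) < 1e-4


class TestKnowledgeFSVR:
    def test_round_trip_serialization(self, default_cohort):
        X = features_matrix(default_cohort)[:40]
        y = labels_vector(default_cohort)[:40]
        model = kfsvr_fit(X, y)
        from wmeeg.regress import KnowledgeFSVRModel

        back = KnowledgeFSVRModel.from_json(model.to_json())
        np.testing.assert_allclose(
            kfsvr_predict(back, X[:5]), kfsvr_predict(model, X[:5]), atol=1e-12
        )

    def test_channel_permutation_consistency(self, default_cohort):
        X = features_matrix(default_cohort)
        y = labels_vector(default_cohort)
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        cols = np.concatenate([[3 * p, 3 * p + 1, 3 * p + 2] for p in perm])
        a = kfsvr_fit(X[:80], y[:80], seed=3)
        b = kfsvr_fit(X[:80][:, cols], y[:80], seed=3)
        np.testing.assert_allclose(
            kfsvr_predict(a, X[80:]), kfsvr_predict(b, X[80:][:, cols]), atol=1e-8
        )

    def test_constant_transform_degenerates_to_constant_predictor(self):
        import itertools

        from wmeeg.fuzzy import FuzzyRuleBase, default_rule_base

        base = default_rule_base()
        constant_rb = FuzzyRuleBase(
            input_terms=base.input_terms,
            rules=[(c, 1) for c in itertools.product(range(3), repeat=3)],
            consequent_terms=base.consequent_terms,
        )
        rng = np.random.default_rng(12)
        X = rng.uniform(0.05, 0.4, size=(30, 30))
        y = rng.normal(size=30)
        model = kfsvr_fit(X, y, rb=constant_rb, gamma=1.0, C=1.0)
        preds = kfsvr_predict(model, rng.uniform(0.05, 0.4, size=(10, 30)))
        assert np.ptp(preds) < 1e-9  # every input maps to the same degree vector

    def test_recovers_signal_at_low_noise(self):
        cfg = SynthConfig(seed=11, noise_sd=0.1, label_noise_sd=0.05, subject_offset_sd=0.2)
        recs = generate_dataset(cfg)
        X, y = features_matrix(recs), labels_vector(recs)
        groups = np.array([r.subject_id for r in recs])
        test = np.isin(groups, sorted(set(groups))[:6])
        model = kfsvr_fit(X[~test], y[~test], groups=groups[~test])
        mse = np.mean((kfsvr_predict(model, X[test]) - y[test]) ** 2)
        assert mse < 0.5 * y.var()


class TestMultiLinearSVR:
    def test_strict_residual_filter(self):
        idx = filter_clustering_set(np.array([0.2, 0.6, 0.4, 0.5]), tau=0.5)
        np.testing.assert_array_equal(idx, [0, 2])

    def test_well_fit_baseline_keeps_everything(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        y = 0.05 * X[:, 0]
        model = mlsvr_fit(X, y, gamma=0.5, C=10.0, seed=0)
        resid = svr_predict(model.baseline, X) - y
        assert filter_clustering_set(resid, 0.5).size == 40

    def test_empty_clustering_set_falls_back_to_baseline(self):
        X = np.zeros((10, 2))
        y = np.tile([10.0, -10.0], 5)
        with pytest.warns(UserWarning):
            model = mlsvr_fit(X, y, gamma=1.0, C=1.0, seed=0)
        assert model.fcm is None and model.chosen_K == 0
        pred = mlsvr_predict(model, X[:2])
        np.testing.assert_allclose(pred, svr_predict(model.baseline, X[:2]))

    def test_fusion_is_convex_combination(self):
        rng = np.random.default_rng(5)
        experts = [
            SVRModel(rng.normal(size=(3, 2)), rng.uniform(-1, 1, 3), 0.1 * k, "linear", None, 1.0, 0.1)
            for k in range(3)
        ]
        from wmeeg.regress import MultiLinearSVRModel

        model = MultiLinearSVRModel(
            baseline=experts[0],
            fcm=FCMModel(rng.normal(size=(3, 2)), m=2.0),
            experts=experts,
            chosen_K=3,
        )
        X = rng.normal(size=(20, 2))
        fused = mlsvr_predict(model, X)
        per = np.column_stack([svr_predict(e, X) for e in experts])
        assert np.all(fused >= per.min(axis=1) - 1e-9)
        assert np.all(fused <= per.max(axis=1) + 1e-9)

    def test_query_at_centroid_uses_that_expert_alone(self):
        rng = np.random.default_rng(6)
        experts = [
            SVRModel(rng.normal(size=(3, 2)), rng.uniform(-1, 1, 3), k, "linear", None, 1.0, 0.1)
            for k in range(2)
        ]
        from wmeeg.regress import MultiLinearSVRModel

        centroids = np.array([[0.0, 0.0], [4.0, 4.0]])
        model = MultiLinearSVRModel(experts[0], FCMModel(centroids, 2.0), experts, chosen_K=2)
        x = centroids[1]
        assert mlsvr_predict(model, x) == pytest.approx(float(svr_predict(experts[1], x)))

    def test_two_regime_data_selects_two_clusters_and_beats_single_linear(self):
        rng = np.random.default_rng(7)
        n = 120
        X = np.vstack(
            [
                rng.uniform(-1, 0, size=(n // 2, 1)),
                rng.uniform(2, 3, size=(n // 2, 1)),
            ]
        )
        X = np.column_stack([X, rng.normal(0, 0.05, size=n)])
        y = np.where(X[:, 0] < 1, 2.0 * X[:, 0], -2.0 * X[:, 0] + 6.0)
        y += 0.1 * rng.normal(size=n)
        test = rng.random(n) < 0.3
        model = mlsvr_fit(X[~test], y[~test], gamma=0.5, C=10.0, seed=0)
        assert model.chosen_K == 2
        mse_ml = np.mean((mlsvr_predict(model, X[test]) - y[test]) ** 2)
        single = svr_fit(X[~test], y[~test], kernel="linear", C=10.0)
        mse_single = np.mean((svr_predict(single, X[test]) - y[test]) ** 2)
        assert mse_ml < mse_single


class TestLasso:
    def test_zero_penalty_recovers_ols(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, 0.0, -0.5]) + 0.2
        model = lasso_fit(X, y, lam=0.0)
        np.testing.assert_allclose(lasso_predict(model, X), y, atol=1e-8)

    def test_huge_penalty_shrinks_to_intercept(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 3))
        y = X[:, 0] + rng.normal(size=60)
        model = lasso_fit(X, y, lam=1e6)
        np.testing.assert_array_equal(model.coef, 0.0)
        np.testing.assert_allclose(lasso_predict(model, X), y.mean(), atol=1e-9)

    def test_single_feature_soft_threshold(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std()
        y = 1.5 * x + 0.1 * rng.normal(size=200)
        y = y - y.mean()
        lam = 0.4
        # coordinate-descent solution for standardized single feature:
        # soft-threshold of the OLS coefficient at lam
        b_ols = (x @ y) / (x @ x)
        expected = np.sign(b_ols) * max(abs(b_ols) - lam, 0.0)
        model = lasso_fit(x[:, None], y, lam=lam)
        assert model.coef[0] == pytest.approx(expected, abs=1e-4)

    def test_cv_choice_learns_signal(self, default_cohort):
        X = features_matrix(default_cohort)
        y = labels_vector(default_cohort)
        model = lasso_fit(X, y, seed=0)
        assert np.mean((lasso_predict(model, X) - y) ** 2) < y.var()


def test_tune_svr_returns_grid_values():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 4))
    y = X[:, 0] + 0.1 * rng.normal(size=60)
    gamma, C = tune_svr(X, y, seed=0)
    from wmeeg.regress import SVR_C_GRID

    assert C in SVR_C_GRID and gamma > 0
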