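import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from siribruise.classify import (
    evaluate,
    knn_cv_select,
    knn_fit_predict,
    lssvm_cv_select,
    lssvm_fit,
    plsda_fit,
)


def two_blobs(rng, n=20, gap=8.0):
    x = np.vstack(
        [rng.normal(0, 1, (n, 2)), rng.normal(gap, 1, (n, 2))]
    )
    y = np.concatenate([-np.ones(n), np.ones(n)])
    return x, y


class TestLssvm:
    def test_separable_blobs_fit_perfectly(self, rng):
        x, y = two_blobs(rng)
        model = lssvm_fit(x, y, gamma=10.0, sigma_k=1.0)
        assert np.all(model.predict(x) == y)

    def test_solution_matches_dense_solver_oracle(self, rng):
        x = rng.normal(0, 1, (6, 3))
        y = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        gamma, sigma_k = 5.0, 2.0
        model = lssvm_fit(x, y, gamma, sigma_k)
        # independent assembly of the KKT system, solved with lapack gesv
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        k = np.exp(-d2 / sigma_k**2)
        a = np.block([[np.zeros((1, 1)), np.ones((1, 6))], [np.ones((6, 1)), k + np.eye(6) / gamma]])
        sol = linalg.solve(a, np.concatenate([[0.0], y]))
        assert abs(model.bias - sol[0]) < 1e-8
        assert np.abs(model.alpha - sol[1:]).max() < 1e-8

    def test_kkt_residual_small_after_fit(self, rng):
        x, y = two_blobs(rng, n=15)
        model = lssvm_fit(x, y, gamma=100.0, sigma_k=1.0)
        assert model.kkt_residual < 1e-8

    def test_cv_selection_returns_grid_minimizer(self, rng):
        x, y = two_blobs(rng, n=12, gap=3.0)
        grid_g = (0.1, 10.0)
        grid_s = (0.5, 5.0)
        gamma, sigma_k, err = lssvm_cv_select(x, y, grid_g, grid_s, folds=4, seed=1)
        # exhaustive re-evaluation of every grid point with the same folds
        errs = {}
        for g in grid_g:
            for s in grid_s:
                _, _, e = lssvm_cv_select(x, y, (g,), (s,), folds=4, seed=1)
                errs[(g, s)] = e
        assert err == min(errs.values())
        assert errs[(gamma, sigma_k)] == err

    def test_invalid_hyperparameters_rejected(self, rng):
        x, y = two_blobs(rng, n=5)
        with pytest.raises(ValueError):
            lssvm_fit(x, y, gamma=-1.0, sigma_k=1.0)
        with pytest.raises(ValueError):
            lssvm_fit(x, np.abs(y), gamma=1.0, sigma_k=1.0)


class TestPlsda:
    def test_one_latent_variable_equals_univariate_regression(self, rng):
        x = rng.normal(0, 1, (30, 1))
        y = (x[:, 0] + rng.normal(0, 0.3, 30) > 0).astype(float)
        model = plsda_fit(x, y, max_lv=1, select="none")
        slope = np.cov(x[:, 0], y, bias=True)[0, 1] / x[:, 0].var()
        intercept = y.mean() - slope * x[:, 0].mean()
        pred_ols = slope * x[:, 0] + intercept
        np.testing.assert_allclose(model.decision_function(x), pred_ols, atol=1e-10)

    def test_full_rank_equals_multiple_linear_regression(self, rng):
        x = rng.normal(0, 1, (25, 4))
        y = (x @ np.array([1.0, -0.5, 0.2, 0.0]) > 0).astype(float)
        model = plsda_fit(x, y, max_lv=4, select="none")
        xc = np.column_stack([np.ones(25), x])
        beta = linalg.lstsq(xc, y)[0]
        np.testing.assert_allclose(
            model.decision_function(x), xc @ beta, atol=1e-8
        )

    def test_loo_selection_reaches_zero_error_on_separable_blobs(self, rng):
        x, ypm = two_blobs(rng, n=15)
        y = (ypm > 0).astype(float)
        model = plsda_fit(x, y, max_lv=2)
        assert np.all(model.predict(x) == y)

    def test_excess_latent_variables_capped(self, rng):
        x = rng.normal(0, 1, (10, 3))
        y = np.array([0.0, 1.0] * 5)
        model = plsda_fit(x, y, max_lv=50, select="none")
        assert model.n_latent <= 3

    def test_matches_sklearn_pls_regression(self, rng):
        """Independent cross-check of the PLS1 core against scikit-learn."""
        from sklearn.cross_decomposition import PLSRegression

        x = rng.normal(0, 1, (40, 6))
        y = (x[:, 0] - x[:, 3] + rng.normal(0, 0.5, 40) > 0).astype(float)
        ours = plsda_fit(x, y, max_lv=3, select="none")
        theirs = PLSRegression(n_components=3, scale=False).fit(x, y)
        np.testing.assert_allclose(
            ours.decision_function(x), theirs.predict(x).ravel(), atol=1e-8
        )


class TestKnn:
    def test_k1_recalls_training_set(self, rng):
        x, y = two_blobs(rng, n=10, gap=3.0)
        assert np.all(knn_fit_predict(x, y, x, 1) == y)

    def test_matches_brute_force_neighbor_oracle(self, rng):
        x_train = rng.normal(0, 1, (30, 4))
        y_train = (rng.random(30) > 0.5).astype(int)
        x_test = rng.normal(0, 1, (12, 4))
        pred = knn_fit_predict(x_train, y_train, x_test, 3)
        for i, xt in enumerate(x_test):
            d = np.sqrt(((x_train - xt) ** 2).sum(1))
            nearest = np.argsort(d, kind="stable")[:3]
            vote = int(y_train[nearest].sum() * 2 > 3)
            assert pred[i] == vote

    def test_even_k_rejected(self, rng):
        x, y = two_blobs(rng, n=5)
        with pytest.raises(ValueError):
            knn_fit_predict(x, y, x, 2)

    def test_cv_selected_k_is_grid_argmin(self, rng):
        x, y = two_blobs(rng, n=15, gap=2.0)
        k, err = knn_cv_select(x, y, k_grid=(1, 3, 5), folds=5, seed=3)
        errs = {kk: knn_cv_select(x, y, k_grid=(kk,), folds=5, seed=3)[1] for kk in (1, 3, 5)}
        assert err == min(errs.values()) and errs[k] == err

    def test_matches_sklearn_on_unambiguous_points(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        x_train = rng.normal(0, 1, (40, 3))
        y_train = (rng.random(40) > 0.5).astype(int)
        x_test = rng.normal(0, 1, (15, 3))
        ours = knn_fit_predict(x_train, y_train, x_test, 5)
        theirs = KNeighborsClassifier(n_neighbors=5).fit(x_train, y_train).predict(x_test)
        np.testing.assert_array_equal(ours, theirs)


def feature_frame(rng, n_per_class=12, gap=6.0):
    rows = []
    for degree, mean in (("S0", 0.0), ("S1", gap), ("S2", gap), ("S3", gap)):
        for i in range(n_per_class):
            vals = rng.normal(mean if degree != "S0" else 0.0, 1.0, 5)
            rows.append(
                {
                    "sample_id": f"{degree}_{i:03d}",
                    "degree": degree,
                    "label": "sound" if degree == "S0" else "bruised",
                    "source_image": "RT",
                    **{f"f{j}": v for j, v in enumerate(vals)},
                }
            )
    return pd.DataFrame(rows)


class TestEvaluate:
    def test_separable_features_reach_perfect_scores(self, rng):
        df = feature_frame(rng)
        report = evaluate(df, model="plsda", degree_scope="ALL", source_image="RT", n_reps=5, seed=1)
        assert report.tp_mean == 100.0
        assert report.tn_mean == 100.0
        assert report.acc_mean == 100.0
        assert report.acc_se == 0.0

    def test_accuracy_arithmetic_from_confusion_counts(self):
        # 29/30 bruised and 28/30 sound correct -> ACC = 57/60 = 95%
        assert (29 + 28) / 60 * 100 == pytest.approx(95.0)

    def test_report_invariant_to_row_order(self, rng):
        df = feature_frame(rng, gap=2.0)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = evaluate(df, model="knn", degree_scope="S1", source_image="RT", n_reps=4, seed=7)
        b = evaluate(shuffled, model="knn", degree_scope="S1", source_image="RT", n_reps=4, seed=7)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_subset_restricts_feature_columns(self, rng):
        df = feature_frame(rng)
        report = evaluate(
            df, model="plsda", degree_scope="ALL", source_image="RT",
            n_reps=3, subset=["f0", "f1"], seed=2,
        )
        assert report.acc_mean > 90.0
        with pytest.raises(ValueError):
            evaluate(df, subset=["nope"], n_reps=2, source_image="RT")

    def test_unknown_scope_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate(feature_frame(rng), degree_scope="S7")
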