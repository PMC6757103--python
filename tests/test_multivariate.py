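"""PCA/OPLS identities, grouped cross-validation, VIP."""

import numpy as np
import pandas as pd
import pytest

from specklestrain import (
    SpecError,
    fit_opls,
    fit_pca,
    loading_classes,
    loso_cv,
    vip_scores,
)


def _scaled(X):
    X = X - X.mean(axis=0)
    return X / X.std(axis=0, ddof=1)


def _random_scaled(n, p, seed):
    rng = np.random.default_rng(seed)
    return _scaled(rng.normal(size=(n, p)))


class TestPCA:
    def test_rank_one_matrix_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=30), rng.normal(size=8))
        model = fit_pca(X - X.mean(axis=0), 3)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_explained_fractions_match_eigendecomposition(self):
        X = _random_scaled(40, 6, seed=1)
        model = fit_pca(X, 5)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            model.explained_variance_ratio, (eigvals / eigvals.sum())[:5], atol=1e-8
        )

    def test_reconstruction_error_equals_unexplained_variance(self):
        X = _random_scaled(25, 7, seed=2)
        Xc = X - X.mean(axis=0)
        model = fit_pca(X, 3)
        recon = model.scores @ model.loadings
        resid = np.sum((Xc - recon) ** 2)
        total = np.sum(Xc**2)
        assert resid / total == pytest.approx(
            1 - model.explained_variance_ratio.sum(), abs=1e-10
        )

    def test_loadings_orthonormal_and_scores_orthogonal(self):
        X = _random_scaled(30, 6, seed=3)
        model = fit_pca(X, 4)
        np.testing.assert_allclose(model.loadings @ model.loadings.T, np.eye(4), atol=1e-10)
        gram = model.scores.T @ model.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_row_permutation_invariance_of_explained_fractions(self):
        X = _random_scaled(30, 6, seed=4)
        rng = np.random.default_rng(5)
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            fit_pca(X, 3).explained_variance_ratio,
            fit_pca(X[perm], 3).explained_variance_ratio,
            atol=1e-10,
        )

    def test_excess_components_rejected(self):
        with pytest.raises(SpecError):
            fit_pca(_random_scaled(5, 10, seed=6), 6)


class TestOPLS:
    def test_response_proportional_to_one_column_fits_perfectly(self):
        # orthogonal columns = "no other structure": the single predictive
        # component must align exactly with the informative column
        rng = np.random.default_rng(7)
        raw = rng.normal(size=(30, 5))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q - q.mean(axis=0)  # zero-mean AND orthogonal columns
        y = 3.0 * X[:, 2]
        model = fit_opls(X, y, n_orthogonal=0)
        assert model.r2y == pytest.approx(1.0, abs=1e-10)

    def test_zero_orthogonal_equals_one_component_pls(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(8)
        X = _random_scaled(40, 10, seed=8)
        y = X @ rng.normal(size=10) + rng.normal(scale=0.5, size=40)
        model = fit_opls(X, y, n_orthogonal=0)
        sk = PLSRegression(n_components=1, scale=False).fit(X, y)
        np.testing.assert_allclose(
            model.predict(X), sk.predict(X).ravel(), atol=1e-10
        )

    def test_orthogonal_scores_uncorrelated_with_response(self):
        rng = np.random.default_rng(9)
        X = _random_scaled(50, 12, seed=9)
        y = X @ rng.normal(size=12) + rng.normal(size=50)
        model = fit_opls(X, y, n_orthogonal=2)
        yc = y - y.mean()
        for k in range(model.n_orthogonal):
            corr = np.corrcoef(model.t_orth[:, k], yc)[0, 1]
            assert abs(corr) < 1e-8

    def test_orthogonal_filtering_cleans_predictive_score(self):
        """Removing a strong y-orthogonal direction must not hurt the
        predictive score's correlation with y (the point of OPLS)."""
        rng = np.random.default_rng(10)
        n = 60
        y = rng.normal(size=n)
        confound = rng.normal(size=n)  # y-orthogonal by construction below
        confound -= confound @ y / (y @ y) * y
        X = np.outer(y, rng.normal(size=8)) + 5.0 * np.outer(confound, rng.normal(size=8))
        X += rng.normal(scale=0.3, size=X.shape)
        X = _scaled(X)
        opls = fit_opls(X, y, n_orthogonal=1)
        pls = fit_opls(X, y, n_orthogonal=0)
        corr_opls = abs(np.corrcoef(opls.t_pred, y)[0, 1])
        corr_pls = abs(np.corrcoef(pls.t_pred, y)[0, 1])
        assert corr_opls >= corr_pls - 1e-12

    def test_constant_response_rejected(self):
        with pytest.raises(SpecError):
            fit_opls(_random_scaled(10, 4, seed=11), np.ones(10))


class TestLosoCV:
    def _grouped_data(self, n_subj=8, per_subj=5, p=6, noise=0.0, seed=12):
        rng = np.random.default_rng(seed)
        n = n_subj * per_subj
        subj = np.repeat(np.arange(n_subj), per_subj)
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + noise * rng.normal(size=n)
        return X, y, subj

    def test_noise_free_linear_response_generalizes(self):
        # one latent direction drives both X and y, so a single predictive
        # component represents the map exactly and held-out subjects are
        # predicted almost perfectly
        rng = np.random.default_rng(12)
        n_subj, per_subj, p = 8, 5, 6
        latent = rng.normal(size=n_subj * per_subj)
        X = np.outer(latent, rng.normal(size=p))
        X += 0.01 * rng.normal(size=X.shape)
        y = 2.0 * latent
        subj = np.repeat(np.arange(n_subj), per_subj)
        cv = loso_cv(X, y, subj, n_orthogonal=0)
        assert cv.q2y >= 0.99

    def test_rmsecv_is_rms_of_fold_residuals(self):
        X, y, subj = self._grouped_data(noise=1.0)
        cv = loso_cv(X, y, subj, n_orthogonal=1)
        resid = cv.predictions["y_true"] - cv.predictions["y_pred"]
        assert cv.rmsecv == pytest.approx(np.sqrt(np.mean(resid**2)), abs=1e-12)

    def test_q2y_definition_identity(self):
        X, y, subj = self._grouped_data(noise=2.0, seed=13)
        cv = loso_cv(X, y, subj, n_orthogonal=1)
        press = np.sum((cv.predictions["y_true"] - cv.predictions["y_pred"]) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert cv.q2y == pytest.approx(1 - press / tss, abs=1e-12)

    def test_fold_assignment_holds_out_whole_subjects(self):
        X, y, subj = self._grouped_data()
        cv = loso_cv(X, y, subj, n_orthogonal=0)
        assert set(cv.predictions["subject"]) == set(subj)

    def test_too_few_subjects_rejected(self):
        X, y, subj = self._grouped_data(n_subj=2)
        with pytest.raises(SpecError):
            loso_cv(X, y, subj)

    def test_permuted_response_has_no_predictive_power(self):
        X, y, subj = self._grouped_data(noise=0.5, seed=14)
        rng = np.random.default_rng(15)
        q2s = []
        for _ in range(10):
            q2s.append(loso_cv(X, rng.permutation(y), subj, n_orthogonal=1).q2y)
        assert np.mean(q2s) <= 0.0


class TestVIP:
    def test_mean_squared_vip_is_one(self):
        X = _random_scaled(30, 9, seed=16)
        y = X @ np.arange(1.0, 10.0)
        model = fit_opls(X, y, n_orthogonal=1)
        vip = vip_scores(model)
        assert np.mean(vip.vip.to_numpy() ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_identical_columns_share_unit_vip(self):
        rng = np.random.default_rng(17)
        col = rng.normal(size=40)
        X = _scaled(np.tile(col[:, None], (1, 6)) + 0.0)
        y = col - col.mean()
        model = fit_opls(X, y, n_orthogonal=0)
        np.testing.assert_allclose(vip_scores(model).vip.to_numpy(), 1.0, atol=1e-10)

    def test_informative_variable_ranks_first(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(60, 10))
        y = 2.0 * X[:, 4] + 0.3 * rng.normal(size=60)
        model = fit_opls(_scaled(X), y, n_orthogonal=0)
        vip = vip_scores(model)
        assert vip.vip.idxmax() == 4
        assert vip.important[4]


def test_cv_score_plot_written(tmp_path):
    from specklestrain import plot_cv_scores

    rng = np.random.default_rng(21)
    X = rng.normal(size=(30, 6))
    y = X @ rng.normal(size=6) + rng.normal(size=30)
    subj = np.repeat(np.arange(6), 5)
    cv = loso_cv(X, y, subj, n_orthogonal=1)
    out = plot_cv_scores(cv, tmp_path / "scores.png")
    assert out.exists() and out.stat().st_size > 0


def test_loading_classes_partition_by_sign_and_magnitude():
    X = _random_scaled(40, 12, seed=19)
    rng = np.random.default_rng(20)
    y = X @ rng.normal(size=12)
    model = fit_opls(X, y, n_orthogonal=1)
    classes = loading_classes(model, [f"v{i}" for i in range(12)])
    assert set(classes.unique()) <= {"Low", "High I", "High II"}
    neg = model.p_pred < 0
    assert (classes.to_numpy()[neg] == "Low").all()
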