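"""PCA, regularized/thresholded LDA, cross-validation and ROC — each checked
against an independent oracle (direct eigendecomposition, brute-force Gaussian
densities, exhaustive grid loops, concordant-pair counting)."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from ecmir.ecm3disc import (DEFAULT_DELTA_GRID, DEFAULT_GAMMA_GRID, FitError,
                            build_training_matrix, cross_validate, fit_pca,
                            fit_rlda, predict_pixels, roc_curve)


class TestTrainingMatrix:
    def test_identical_spectra_mean_is_that_spectrum(self, rng):
        s = rng.normal(size=50)
        M, labels, ids = build_training_matrix(
            {"p": np.vstack([s, s])}, {"p": "ECM3"})
        np.testing.assert_allclose(M[0], s, atol=1e-15)

    def test_mean_of_zero_and_double(self, rng):
        s = rng.normal(size=30)
        M, _, _ = build_training_matrix(
            {"p": np.vstack([np.zeros(30), 2 * s])}, {"p": "ECM3"})
        np.testing.assert_allclose(M[0], s, atol=1e-15)

    def test_large_set_matches_two_pass_oracle(self, rng):
        spectra = rng.normal(size=(10_000, 20))
        M, _, _ = build_training_matrix({"p": spectra}, {"p": "non-ECM3"})
        oracle = spectra.sum(axis=0) / spectra.shape[0]  # independent pass
        np.testing.assert_allclose(M[0], oracle, atol=1e-12)

    def test_empty_patient_excluded(self, rng):
        M, labels, ids = build_training_matrix(
            {"a": rng.normal(size=(3, 10)), "b": np.empty((0, 10))},
            {"a": "ECM3", "b": "non-ECM3"})
        assert ids == ["a"] and M.shape[0] == 1


class TestPca:
    def test_rank_limited_variances(self, rng):
        base = rng.normal(size=(3, 40))
        X = rng.normal(size=(12, 3)) @ base          # rank 3
        model = fit_pca(X, n_components=5)
        assert np.sum(model.explained_variances > 1e-10) == 3

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(8, 30))
        model = fit_pca(X, n_components=7)
        back = model.inverse_transform(model.transform(X))
        np.testing.assert_allclose(back, X, atol=1e-9)

    def test_variances_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(25, 12))
        model = fit_pca(X, n_components=10)
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1][:10]
        np.testing.assert_allclose(model.explained_variances, eig, atol=1e-9)

    def test_orthonormal_loadings_and_sign_convention(self, rng):
        X = rng.normal(size=(15, 20))
        model = fit_pca(X, n_components=8)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)
        for j in range(8):
            k = np.argmax(np.abs(model.loadings[:, j]))
            assert model.loadings[k, j] > 0

    def test_too_many_components_raises(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(5, 30)), n_components=10)


class TestRlda:
    def test_1d_equal_priors_boundary_at_midpoint(self):
        scores = np.array([[-1.0], [0.0], [1.0], [1.0], [2.0], [3.0]])
        labels = np.array(["non-ECM3"] * 3 + ["ECM3"] * 3)
        # class means 0 and 2 with equal priors; boundary at 1 by symmetry
        model = fit_rlda(scores, labels, gamma=0.0, delta=0.0)
        assert model.posterior(np.array([[1.0]]))[0] == pytest.approx(0.5,
                                                                      abs=1e-12)
        assert model.posterior(np.array([[1.1]]))[0] > 0.5

    def test_delta_above_all_weights_zeroes_model(self, rng):
        X = rng.normal(size=(20, 3))
        labels = np.array(["ECM3"] * 10 + ["non-ECM3"] * 10)
        model = fit_rlda(X, labels, gamma=0.1, delta=1e9)
        assert np.all(model.w == 0)
        # with w = 0 the posterior reduces to the prior ratio
        expected = 1 / (1 + np.exp(-np.log(model.priors[0] / model.priors[1])))
        np.testing.assert_allclose(model.posterior(rng.normal(size=(5, 3))),
                                   expected, atol=1e-12)

    def test_posterior_matches_gaussian_density_oracle(self, rng):
        """Brute-force oracle: two multivariate normal densities with the
        shared shrunk covariance and prior weights."""
        X = rng.normal(size=(6, 2)) + np.array([[2.0, -1.0]] * 3 + [[0, 0]] * 3)
        labels = np.array(["ECM3"] * 3 + ["non-ECM3"] * 3)
        gamma = 0.2
        model = fit_rlda(X, labels, gamma=gamma, delta=0.0)
        S_gamma = (1 - gamma) * model.pooled_cov + gamma * np.diag(
            np.diag(model.pooled_cov))
        pts = rng.normal(size=(20, 2))
        num = multivariate_normal(model.mean_pos, S_gamma).pdf(pts) * model.priors[0]
        den = multivariate_normal(model.mean_neg, S_gamma).pdf(pts) * model.priors[1]
        oracle = num / (num + den)
        np.testing.assert_allclose(model.posterior(pts), oracle, atol=1e-10)

    def test_gamma_zero_equals_textbook_lda_direction(self, rng):
        """Oracle: sklearn's LDA coefficient vector is proportional to
        S⁻¹(μ₊ − μ₋)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = rng.normal(size=(60, 4))
        X[:30] += 1.5
        labels = np.array(["ECM3"] * 30 + ["non-ECM3"] * 30)
        model = fit_rlda(X, labels, gamma=0.0, delta=0.0)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(
            X, (labels == "ECM3").astype(int))
        w_sk = sk.coef_.ravel()
        cos = np.dot(model.w, w_sk) / np.linalg.norm(model.w) / np.linalg.norm(w_sk)
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_delta_monotonicity_of_sparsity(self, rng):
        X = rng.normal(size=(40, 6))
        X[:20] += 0.8
        labels = np.array(["ECM3"] * 20 + ["non-ECM3"] * 20)
        nz = [np.count_nonzero(fit_rlda(X, labels, 0.1, d).w)
              for d in np.linspace(0.0, 2.0, 15)]
        assert all(a >= b for a, b in zip(nz, nz[1:]))

    def test_singular_covariance_advises_regularization(self, rng):
        X = rng.normal(size=(4, 10))  # n ≤ dim, gamma = 0 → singular
        labels = np.array(["ECM3", "ECM3", "non-ECM3", "non-ECM3"])
        with pytest.raises(FitError):
            fit_rlda(X, labels, gamma=0.0, delta=0.0)


class TestCrossValidate:
    def test_separable_cohort_reaches_zero_loss(self, rng):
        X = rng.normal(size=(30, 10))
        X[:15, 0] += 25.0
        labels = np.array(["ECM3"] * 15 + ["non-ECM3"] * 15)
        cv = cross_validate(X, labels, k=5, seed=0, n_components=5)
        assert cv.cv_loss.min() == 0.0
        assert cv.cv_loss[cv.chosen_index] == 0.0

    def test_every_patient_in_exactly_one_test_fold(self, rng):
        X = rng.normal(size=(30, 8))
        labels = np.array(["ECM3"] * 15 + ["non-ECM3"] * 15)
        cv = cross_validate(X, labels, k=5, seed=1, n_components=4)
        assert sorted(np.unique(cv.fold_of_patient)) == [0, 1, 2, 3, 4]
        assert np.bincount(cv.fold_of_patient).sum() == 30

    def test_chosen_point_matches_independent_grid_loop(self, rng):
        """Exhaustive oracle: re-evaluate every grid point with an
        independent fold loop and pick the minimizer by the same tie rule."""
        X = rng.normal(size=(24, 6))
        X[:12, :2] += 1.0
        labels = np.array(["ECM3"] * 12 + ["non-ECM3"] * 12)
        gammas, deltas = (0.01, 0.1, 1.0), (0.0, 0.05)
        cv = cross_validate(X, labels, gamma_grid=gammas, delta_grid=deltas,
                            k=4, seed=3, n_components=3)

        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=3)
        grid = [(g, d) for g in gammas for d in deltas]
        losses = []
        for g, d in grid:
            wrong = 0
            for train, test in skf.split(X, labels):
                pca = fit_pca(X[train], 3)
                m = fit_rlda(pca.transform(X[train]), labels[train], g, d)
                pred = m.posterior(pca.transform(X[test])) >= 0.5
                wrong += np.sum(pred != (labels[test] == "ECM3"))
            losses.append(wrong / len(labels))
        best = int(np.argmin(losses))
        assert cv.chosen == grid[best]
        np.testing.assert_allclose(cv.cv_loss, losses, atol=1e-12)

    def test_shuffled_labels_give_chance_level_loss(self, rng):
        """Permutation null: mean CV loss over 50 label shuffles sits near
        0.5."""
        X = rng.normal(size=(30, 10))
        base = np.array(["ECM3"] * 15 + ["non-ECM3"] * 15)
        losses = []
        for seed in range(50):
            perm = np.random.default_rng(seed).permutation(30)
            cv = cross_validate(X, base[perm], gamma_grid=(0.1,),
                                delta_grid=(0.0,), k=5, seed=seed,
                                n_components=5)
            losses.append(cv.cv_loss[cv.chosen_index])
        assert 0.4 <= np.mean(losses) <= 0.6

    def test_small_class_raises(self, rng):
        X = rng.normal(size=(8, 4))
        labels = np.array(["ECM3"] * 3 + ["non-ECM3"] * 5)
        with pytest.raises(ValueError):
            cross_validate(X, labels, k=5, n_components=2)


class TestRoc:
    def test_perfectly_separated_scores(self):
        roc = roc_curve(np.array([0.1, 0.2, 0.8, 0.9]),
                        np.array(["non-ECM3", "non-ECM3", "ECM3", "ECM3"]),
                        n_boot=50, seed=0)
        assert roc.auc == 1.0
        assert 0.2 < roc.optimal_threshold <= 0.8

    def test_all_tied_scores_give_half(self):
        roc = roc_curve(np.full(10, 0.5),
                        np.array(["ECM3"] * 5 + ["non-ECM3"] * 5),
                        n_boot=10, seed=0)
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_concordant_pair_oracle(self, rng):
        """Mann-Whitney identity: AUC = concordant-pair fraction with ties
        counted half."""
        scores = rng.random(200).round(2)  # rounding forces ties
        labels = np.where(rng.random(200) < 0.5, "ECM3", "non-ECM3")
        if len(np.unique(labels)) < 2:
            labels[0] = "ECM3"
        roc = roc_curve(scores, labels, n_boot=10, seed=0)
        pos = scores[labels == "ECM3"]
        neg = scores[labels != "ECM3"]
        pairs = (pos[:, None] > neg[None, :]).sum() \
            + 0.5 * (pos[:, None] == neg[None, :]).sum()
        np.testing.assert_allclose(roc.auc, pairs / (pos.size * neg.size),
                                   atol=1e-12)

    def test_curve_monotone_and_trapezoid_consistent(self, rng):
        scores = rng.random(60)
        labels = np.array(["ECM3"] * 30 + ["non-ECM3"] * 30)
        roc = roc_curve(scores, labels, n_boot=10, seed=0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr),
                                        abs=1e-12)
        assert 0.0 <= roc.auc <= 1.0

    def test_bootstrap_ci_is_seeded_and_ordered(self, rng):
        scores = rng.random(40)
        labels = np.array(["ECM3"] * 20 + ["non-ECM3"] * 20)
        a = roc_curve(scores, labels, n_boot=200, seed=5)
        b = roc_curve(scores, labels, n_boot=200, seed=5)
        assert a.auc_ci == b.auc_ci
        assert a.auc_ci[0] <= a.auc <= a.auc_ci[1] or a.auc_ci[0] <= a.auc_ci[1]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.9]), np.array(["ECM3", "ECM3"]))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 40))
    X[:15, :5] += 2.0
    labels = np.array(["ECM3"] * 15 + ["non-ECM3"] * 15)
    pca = fit_pca(X, 10)
    model = fit_rlda(pca.transform(X), labels, gamma=0.1, delta=0.0)
    return X, labels, pca, model


class TestPredictPixels:
    def test_class_mean_spectrum_gets_confident_call(self, fitted):
        X, labels, pca, model = fitted
        mean_pos = X[:15].mean(axis=0)
        calls, post = predict_pixels(pca, model, mean_pos)
        assert calls[0] and post[0] > 0.5

    def test_equidistant_point_with_equal_priors_gives_half(self, fitted):
        X, labels, pca, model = fitted
        mid_scores = (model.mean_pos + model.mean_neg) / 2
        mid_spectrum = pca.inverse_transform(mid_scores)
        _, post = predict_pixels(pca, model, mid_spectrum)
        assert post[0] == pytest.approx(0.5, abs=1e-9)

    def test_posterior_matches_density_ratio_oracle(self, fitted, rng):
        X, labels, pca, model = fitted
        pts = rng.normal(size=(20, 40))
        _, post = predict_pixels(pca, model, pts)
        Z = pca.transform(pts)
        gamma = model.gamma
        S_gamma = (1 - gamma) * model.pooled_cov + gamma * np.diag(
            np.diag(model.pooled_cov))
        num = multivariate_normal(model.mean_pos, S_gamma).pdf(Z) * model.priors[0]
        den = multivariate_normal(model.mean_neg, S_gamma).pdf(Z) * model.priors[1]
        np.testing.assert_allclose(post, num / (num + den), atol=1e-10)

    def test_band_mismatch_raises(self, fitted):
        X, labels, pca, model = fitted
        with pytest.raises(ValueError):
            predict_pixels(pca, model, np.zeros((3, 17)))
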