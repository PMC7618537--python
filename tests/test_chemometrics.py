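"""PCA, confidence ellipses, T²/Q outlier screening and PLS-DA, checked
against brute-force decompositions and independent library oracles."""

import numpy as np
import pytest

import sorscreen as sc
from sorscreen.dataset import DegenerateDataError
from sorscreen import chemometrics


class TestPca:
    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 50))
        model = chemometrics.pca_fit(X, 5)
        w, V = np.linalg.eigh(np.cov(X, rowvar=False, ddof=1))
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        for i in range(5):
            v = V[:, i]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            np.testing.assert_allclose(model.loadings[i], v, atol=1e-8)
            assert model.explained_variance[i] == pytest.approx(w[i], abs=1e-8)

    def test_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 40))
        ours = chemometrics.pca_fit(X, 4)
        ref = sklearn_pca(n_components=4).fit(X)
        for i in range(4):
            sign = np.sign(ref.components_[i] @ ours.loadings[i])
            np.testing.assert_allclose(ours.loadings[i],
                                       sign * ref.components_[i], atol=1e-8)
        np.testing.assert_allclose(ours.explained_variance_ratio,
                                   ref.explained_variance_ratio_, atol=1e-10)

    def test_rank_one_matrix(self):
        u = np.outer(np.arange(1.0, 9.0), np.linspace(1, 2, 30))
        model = chemometrics.pca_fit(u, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 6))
        model = chemometrics.pca_fit(X, 6)
        recon = model.scores @ model.loadings
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-8)

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(3)
        model = chemometrics.pca_fit(rng.standard_normal((15, 20)), 5)
        np.testing.assert_allclose(model.loadings @ model.loadings.T,
                                   np.eye(5), atol=1e-8)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_component_budget_enforced(self):
        with pytest.raises(ValueError):
            chemometrics.pca_fit(np.random.default_rng(0).random((5, 10)), 5)


class TestConfidenceEllipse:
    def test_chi2_radius_for_identity_covariance(self):
        # unit-covariance scores: circular boundary of radius sqrt(χ²₂(0.95))
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((2000, 2))
        ell = chemometrics.confidence_ellipse(pts, level=0.95)
        assert np.sqrt(ell.boundary_mahalanobis_sq) == pytest.approx(
            2.4477, abs=1e-3)

    def test_coverage_matches_level(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((100_000, 2))
        ell = chemometrics.confidence_ellipse(pts)
        assert np.mean(ell.contains(pts)) == pytest.approx(0.95, abs=0.005)

    def test_two_points_degenerate(self):
        with pytest.raises(DegenerateDataError):
            chemometrics.confidence_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateDataError):
            chemometrics.confidence_ellipse(pts)

    def test_boundary_points_lie_on_boundary(self):
        rng = np.random.default_rng(4)
        pts = rng.multivariate_normal([1, -2], [[2, 0.5], [0.5, 1]], 500)
        ell = chemometrics.confidence_ellipse(pts)
        boundary = ell.boundary_points(64)
        np.testing.assert_allclose(ell.mahalanobis_sq(boundary),
                                   ell.boundary_mahalanobis_sq, rtol=1e-9)

    def test_hotelling_form_wider_at_small_n(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((10, 2))
        chi2_ell = chemometrics.confidence_ellipse(pts, form="chi2")
        f_ell = chemometrics.confidence_ellipse(pts, form="hotelling")
        assert f_ell.boundary_mahalanobis_sq > chi2_ell.boundary_mahalanobis_sq


class TestOutlierScreen:
    def test_injected_spike_is_the_only_flag(self, genuine_50):
        bad = sc.inject_outlier(genuine_50, 7, "spike", seed=0)
        report = chemometrics.outlier_screen(bad.matrix, 3, 0.99)
        assert report.flagged_rows.tolist() == [7]

    def test_nominal_false_positive_rate(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10_000, 10))
        report = chemometrics.outlier_screen(X, 3, 0.99)
        assert 0.005 <= report.flags.mean() <= 0.03

    def test_mean_duplicate_row_not_flagged(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 8))
        X = np.vstack([X, X.mean(axis=0)])
        report = chemometrics.outlier_screen(X, 3, 0.99)
        assert not report.flags[-1]

    def test_flag_rule_is_union_of_t2_and_q(self, genuine_50):
        report = chemometrics.outlier_screen(genuine_50.matrix, 3, 0.99)
        np.testing.assert_array_equal(
            report.flags,
            (report.t2 > report.t2_limit)
            | (report.q > report.q_limit + 1e-9),
        )

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            chemometrics.outlier_screen(np.eye(5), 3)


class TestPlsda:
    def test_separable_1d_perfect_training_accuracy(self):
        X = np.concatenate([np.linspace(0, 1, 10),
                            np.linspace(4, 5, 10)])[:, None]
        y = np.repeat([0.0, 1.0], 10)
        model = chemometrics.plsda_fit(X, y, 1)
        _, calls = chemometrics.plsda_predict(model, X)
        np.testing.assert_array_equal(calls, y == 1)

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 8))
        y = (rng.standard_normal(30) > 0).astype(float)
        model = chemometrics.plsda_fit(X, y, 8)
        resp, _ = chemometrics.plsda_predict(model, X)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(resp, Xc @ beta + y.mean(), atol=1e-6)

    def test_matches_sklearn_pls_regression(self):
        PLSRegression = pytest.importorskip(
            "sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 25))
        y = (rng.standard_normal(40) > 0).astype(float)
        ours = chemometrics.plsda_fit(X, y, 4)
        resp, _ = chemometrics.plsda_predict(ours, X)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(resp, ref.predict(X).ravel(), atol=1e-8)

    def test_nested_coefficients_match_refits(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((25, 12))
        y = (rng.standard_normal(25) > 0).astype(float)
        full = chemometrics.plsda_fit(X, y, 6)
        for k in range(1, 7):
            refit = chemometrics.plsda_fit(X, y, k)
            np.testing.assert_allclose(full.coefficients_upto(k),
                                       refit.coefficients, atol=1e-10)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((10, 4))
        with pytest.raises(ValueError):
            chemometrics.plsda_fit(X, np.ones(10), 2)

    def test_threshold_tie_called_positive(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = chemometrics.plsda_fit(X, np.array([0.0, 0.0, 1.0, 1.0]), 1)
        model.threshold = float(
            chemometrics.plsda_predict(model, X)[0][1])
        resp, calls = chemometrics.plsda_predict(model, X[[1]])
        assert resp[0] == model.threshold and calls[0]

    def test_empty_input_empty_output(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = chemometrics.plsda_fit(X, np.array([0.0, 0.0, 1.0, 1.0]), 1)
        resp, calls = chemometrics.plsda_predict(model, np.empty((0, 1)))
        assert resp.size == 0 and calls.size == 0

    def test_channel_mismatch_rejected(self):
        X = np.random.default_rng(0).random((10, 4))
        y = np.repeat([0.0, 1.0], 5)
        model = chemometrics.plsda_fit(X, y, 2)
        with pytest.raises(ValueError):
            chemometrics.plsda_predict(model, np.zeros((2, 5)))


class TestCrossValidate:
    def test_every_sample_predicted_exactly_once(self, saline_study):
        _, _, _, pre = saline_study
        y = (pre.labels == "saline").astype(float)
        cv = chemometrics.cross_validate(pre.matrix, y, n_latent=2,
                                         vials=pre.vials)
        tested = np.concatenate([f["test_rows"] for f in cv.folds])
        assert sorted(tested) == list(range(pre.n_spectra))
        assert cv.tp + cv.fp + cv.tn + cv.fn == pre.n_spectra

    def test_vial_never_straddles_folds(self, saline_study):
        _, _, _, pre = saline_study
        y = (pre.labels == "saline").astype(float)
        cv = chemometrics.cross_validate(pre.matrix, y, n_latent=2,
                                         vials=pre.vials)
        for fold in cv.folds:
            assert len(set(pre.vials[fold["test_rows"]])) == 1

    def test_well_separated_classes_score_perfectly(self, saline_study):
        _, _, _, pre = saline_study
        y = (pre.labels == "saline").astype(float)
        cv = chemometrics.cross_validate(pre.matrix, y, vials=pre.vials)
        assert cv.sensitivity == 100.0
        assert cv.specificity == 100.0

    def test_lovo_needs_two_vials_per_class(self):
        rng = np.random.default_rng(0)
        X = rng.random((8, 5))
        y = np.repeat([0.0, 1.0], 4)
        vials = np.array(["a", "a", "b", "b", "c", "c", "c", "c"], dtype=object)
        with pytest.raises(ValueError):
            chemometrics.cross_validate(X, y, n_latent=1, vials=vials)

    def test_stratified_scheme_partitions(self):
        rng = np.random.default_rng(1)
        X = rng.random((30, 6))
        y = np.repeat([0.0, 1.0], 15)
        cv = chemometrics.cross_validate(X, y, n_latent=1,
                                         scheme="stratified-k-fold",
                                         n_folds=5, seed=0)
        tested = np.concatenate([f["test_rows"] for f in cv.folds])
        assert sorted(tested) == list(range(30))

    def test_unknown_scheme_rejected(self):
        X = np.random.default_rng(0).random((10, 4))
        y = np.repeat([0.0, 1.0], 5)
        with pytest.raises(ValueError):
            chemometrics.cross_validate(X, y, n_latent=1, scheme="bootstrap")


class TestConfusionMetrics:
    def test_perfect_counts(self):
        calls = np.repeat([True, False], 6)
        truth = np.repeat([True, False], 6)
        assert chemometrics.confusion_metrics(calls, truth) == (100.0, 100.0)

    def test_five_of_six_sensitivity(self):
        truth = np.array([True] * 6 + [False] * 6)
        calls = np.array([True] * 5 + [False] + [False] * 6)
        sens, spec = chemometrics.confusion_metrics(calls, truth)
        assert sens == pytest.approx(83.33, abs=0.01)
        assert spec == 100.0

    def test_no_positives_yields_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            sens, spec = chemometrics.confusion_metrics(
                np.array([False, True]), np.array([False, False]))
        assert np.isnan(sens)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chemometrics.confusion_metrics([True], [True, False])
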