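"""Classifier family: metric formulas, PCA, covariance, and a full
brute-force oracle over every template scheme x metric combination."""

import numpy as np
import pytest

from moviemvpa import (
    ClassifierSpec,
    average_runs,
    distance,
    estimate_within_class_cov,
    fit,
    fit_pca,
    predict,
    project,
)

from conftest import make_runs


class TestDistance:
    def test_correlation_identity_antiparallel_orthogonal(self):
        y = np.array([1.0, 2.0, 3.0])
        assert distance(y, y, "correlation") == pytest.approx(0.0, abs=1e-12)
        assert distance(y, -y, "correlation") == pytest.approx(2.0)
        assert distance([1.0, 0.0], [0.0, 1.0], "correlation") == pytest.approx(1.0)

    def test_euclidean_is_squared(self):
        assert distance([0.0, 0.0], [3.0, 4.0], "euclidean") == pytest.approx(25.0)

    def test_mahalanobis_identity_cov_equals_squared_euclidean(self):
        assert distance(
            [3.0, 4.0], [0.0, 0.0], "mahalanobis", np.eye(2)
        ) == pytest.approx(25.0)

    def test_normalized_euclidean_hand_value(self):
        # sum (y_n - mu_n)^2 / Sigma_nn = 4/1 + 4/4 = 5
        assert distance(
            [2.0, 2.0], [0.0, 0.0], "normalized_euclidean", np.array([1.0, 4.0])
        ) == pytest.approx(5.0)

    def test_zero_norm_correlation_rejected(self):
        with pytest.raises(ValueError):
            distance([0.0, 0.0], [1.0, 1.0], "correlation")

    def test_cov_required_iff_metric_needs_it(self):
        with pytest.raises(ValueError):
            distance([1.0], [0.0], "mahalanobis")
        with pytest.raises(ValueError):
            distance([1.0], [0.0], "euclidean", np.eye(1))

    def test_non_positive_definite_cov_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError):
            distance([1.0, 0.0], [0.0, 0.0], "mahalanobis", bad)


class TestSpec:
    @pytest.mark.parametrize(
        "name,scheme,metric,n_pcs",
        [
            ("NNC", "nearest_neighbor", "correlation", None),
            ("NNE", "nearest_neighbor", "euclidean", None),
            ("NME", "nearest_mean", "euclidean", None),
            ("GNB64", "nearest_mean", "normalized_euclidean", 64),
            ("LDA32", "nearest_mean", "mahalanobis", 32),
        ],
    )
    def test_name_round_trip(self, name, scheme, metric, n_pcs):
        spec = ClassifierSpec.from_name(name)
        assert (spec.scheme, spec.metric, spec.n_pcs) == (scheme, metric, n_pcs)
        assert spec.name == name

    def test_mahalanobis_requires_pca(self):
        with pytest.raises(ValueError):
            ClassifierSpec(scheme="nearest_mean", metric="mahalanobis")

    def test_nearest_neighbor_restrictions(self):
        with pytest.raises(ValueError):
            ClassifierSpec(scheme="nearest_neighbor", metric="normalized_euclidean")
        with pytest.raises(ValueError):
            ClassifierSpec(scheme="nearest_neighbor", metric="euclidean", n_pcs=4)

    def test_covariance_mode_implied(self):
        assert ClassifierSpec.from_name("LDA8").covariance_mode == "pooled"
        assert ClassifierSpec.from_name("GNB").covariance_mode == "diagonal"
        assert ClassifierSpec.from_name("NME").covariance_mode == "none"


class TestAverageRuns:
    def test_single_run_identity(self, toy_runs):
        np.testing.assert_array_equal(average_runs(toy_runs[:1]), toy_runs[0].data)

    def test_opposite_runs_cancel(self):
        a = np.arange(12.0).reshape(4, 3)
        runs = make_runs([a, -a])
        np.testing.assert_allclose(average_runs(runs), 0.0)

    def test_elementwise_mean_oracle(self):
        rng = np.random.default_rng(21)
        arrays = [rng.standard_normal((6, 4)) for _ in range(7)]
        got = average_runs(make_runs(arrays))
        for c in range(6):
            for v in range(4):
                assert got[c, v] == pytest.approx(
                    sum(a[c, v] for a in arrays) / 7, rel=1e-12
                )


class TestPca:
    def test_rank_one_recovery(self):
        u = np.array([1.0, -1.0, 2.0, 0.0])
        v = np.array([3.0, 0.0, 4.0])
        centroids = np.outer(u - u.mean(), v)  # column-centered rank-1
        pca = fit_pca(centroids, 1)
        direction = v / np.linalg.norm(v)
        assert abs(abs(pca.components[:, 0] @ direction) - 1.0) < 1e-8

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(22)
        centroids = rng.standard_normal((6, 10))
        pca = fit_pca(centroids, 5)
        scores = project(centroids, pca)
        recon = scores @ pca.components.T + pca.mean
        np.testing.assert_allclose(recon, centroids, atol=1e-6)

    def test_orthonormal_and_sorted(self):
        rng = np.random.default_rng(23)
        pca = fit_pca(rng.standard_normal((8, 20)), 5)
        np.testing.assert_allclose(
            pca.components.T @ pca.components, np.eye(5), atol=1e-8
        )
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)

    def test_k_beyond_rank_reports_attainable(self):
        centroids = np.outer(np.arange(5.0), np.ones(8))  # rank 1 after centering
        with pytest.raises(ValueError, match="rank"):
            fit_pca(centroids, 3)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(24)
        centroids = rng.standard_normal((6, 9))
        p1 = fit_pca(centroids, 3)
        p2 = fit_pca(centroids.copy(), 3)
        np.testing.assert_array_equal(p1.components, p2.components)
        for k in range(3):
            j = np.abs(p1.components[:, k]).argmax()
            assert p1.components[j, k] > 0

    def test_projecting_mean_gives_zero(self):
        rng = np.random.default_rng(25)
        pca = fit_pca(rng.standard_normal((6, 7)), 3)
        np.testing.assert_allclose(project(pca.mean[None, :], pca), 0.0, atol=1e-10)

    def test_full_rank_projection_is_isometry(self):
        rng = np.random.default_rng(26)
        data = rng.standard_normal((20, 50))
        centroids = rng.standard_normal((20, 50))
        pca = fit_pca(centroids, 19)
        scores = project(data, pca)
        # distances between rows preserved up to the rank of the basis
        from scipy.spatial.distance import pdist

        span = (centroids - centroids.mean(0))  # rows live in a 19-dim space
        proj_back = (data - pca.mean) @ pca.components @ pca.components.T
        d_full = pdist(proj_back)
        d_pc = pdist(scores)
        np.testing.assert_allclose(d_pc, d_full, rtol=1e-8, atol=1e-8)


class TestWithinClassCov:
    def test_iid_residuals_recover_isotropic(self):
        rng = np.random.default_rng(27)
        sigma = 1.7
        centroids = np.zeros((200, 2))
        runs = [sigma * rng.standard_normal((200, 2)) for _ in range(10)]
        cov = estimate_within_class_cov(runs, centroids, "pooled")
        np.testing.assert_allclose(cov, sigma**2 * np.eye(2), rtol=0.1, atol=0.15)

    def test_diagonal_equals_pooled_diagonal(self):
        rng = np.random.default_rng(28)
        centroids = rng.standard_normal((6, 3))
        runs = [centroids + rng.standard_normal((6, 3)) for _ in range(4)]
        diag = estimate_within_class_cov(runs, centroids, "diagonal")
        full = estimate_within_class_cov(runs, centroids, "pooled")
        np.testing.assert_allclose(diag, np.diag(full), rtol=1e-10)

    def test_zero_residuals_rejected(self):
        centroids = np.arange(6.0).reshape(3, 2)
        runs = [centroids.copy(), centroids.copy()]
        with pytest.raises(ValueError):
            estimate_within_class_cov(runs, centroids, "pooled")

    def test_low_degrees_of_freedom_warns(self):
        rng = np.random.default_rng(29)
        centroids = rng.standard_normal((2, 8))
        runs = [centroids + rng.standard_normal((2, 8)) for _ in range(2)]
        with pytest.warns(UserWarning, match="degrees of freedom"):
            estimate_within_class_cov(runs, centroids, "pooled")


class TestFitPredict:
    def test_single_run_nme_centroids(self, toy_runs):
        froi = np.array([0, 2, 4])
        model = fit(toy_runs[:1], ClassifierSpec.from_name("NME"), froi)
        np.testing.assert_array_equal(model.centroids, toy_runs[0].data[:, froi])

    def test_self_match_is_perfect(self, toy_runs):
        froi = np.arange(5)
        model = fit(toy_runs[:1], ClassifierSpec.from_name("NME"), froi)
        result = predict(model, toy_runs[0])
        np.testing.assert_array_equal(result.predicted, toy_runs[0].labels)

    def test_constant_data_ties_break_low(self):
        runs = make_runs([np.ones((4, 3)), np.ones((4, 3))])
        model = fit(runs[:1], ClassifierSpec.from_name("NME"), np.arange(3))
        result = predict(model, runs[1])
        assert np.all(result.predicted == 0)
        assert result.n_ties == 4

    def test_nn_stores_per_run_templates(self, toy_runs):
        model = fit(toy_runs, ClassifierSpec.from_name("NNC"), np.arange(5))
        assert len(model.training_templates) == 3
        assert all(t.shape == (3, 5) for t in model.training_templates)

    def test_lda_covariance_positive_definite(self, small_preprocessed):
        dataset, _ = small_preprocessed
        model = fit(dataset.runs[:3], ClassifierSpec.from_name("LDA16"), np.arange(200))
        eigvals = np.linalg.eigvalsh(model.pooled_cov)
        assert model.pooled_cov.shape == (16, 16)
        assert eigvals.min() > 0

    def test_npcs_clipped_to_small_froi(self, toy_runs):
        model = fit(toy_runs, ClassifierSpec.from_name("NME64"), np.arange(5))
        assert model.pca.n_components == 2  # min(C-1, |froi|) = 2


class TestIdentities:
    """Structural equivalences between metrics, spaces, and conventions."""

    def _scores(self, rng, n=12, k=4):
        centroids = rng.standard_normal((n, k)) * 3
        runs = [centroids + rng.standard_normal((n, k)) for _ in range(3)]
        test = centroids + rng.standard_normal((n, k))
        return centroids, runs, test

    def test_squared_vs_rooted_same_argmin(self):
        rng = np.random.default_rng(31)
        centroids, _, test = self._scores(rng)
        from moviemvpa.classify import _distance_matrix

        sq = _distance_matrix(test, centroids, "euclidean")
        np.testing.assert_array_equal(sq.argmin(axis=1), np.sqrt(sq).argmin(axis=1))

    def test_mahalanobis_identity_cov_matches_euclidean(self):
        rng = np.random.default_rng(32)
        centroids, _, test = self._scores(rng)
        from moviemvpa.classify import _distance_matrix

        d_e = _distance_matrix(test, centroids, "euclidean")
        d_m = _distance_matrix(test, centroids, "mahalanobis", np.eye(4))
        np.testing.assert_allclose(d_m, d_e, rtol=1e-8)

    def test_gnb_equals_lda_for_diagonal_covariance(self):
        rng = np.random.default_rng(33)
        centroids, _, test = self._scores(rng)
        diag = np.array([0.5, 1.0, 2.0, 4.0])
        from moviemvpa.classify import _distance_matrix

        d_gnb = _distance_matrix(test, centroids, "normalized_euclidean", diag)
        d_lda = _distance_matrix(test, centroids, "mahalanobis", np.diag(diag))
        np.testing.assert_allclose(d_gnb, d_lda, rtol=1e-8)

    def test_full_rank_pc_space_euclidean_matches_voxel_space(self, toy_runs):
        froi = np.arange(5)
        voxel = predict(fit(toy_runs[:2], ClassifierSpec.from_name("NME"), froi), toy_runs[2])
        pc = predict(fit(toy_runs[:2], ClassifierSpec.from_name("NME2"), froi), toy_runs[2])
        # C=3 classes -> 2 PCs span the centered centroid space exactly
        np.testing.assert_array_equal(voxel.predicted, pc.predicted)


# --------------------------------------------------------------------------
# Brute-force oracle: naive, loop-based reimplementation of every classifier.

RIDGE = 1e-8


def _bf_class_matrix(run):
    out = np.empty_like(run.data)
    for row, label in enumerate(run.labels):
        out[label] = run.data[row]
    return out


def _bf_dist(y, x, metric, cov=None):
    if metric == "correlation":
        return 1.0 - float(np.dot(y, x) / (np.linalg.norm(y) * np.linalg.norm(x)))
    if metric == "euclidean":
        return float(sum((a - b) ** 2 for a, b in zip(y, x)))
    if metric == "normalized_euclidean":
        return float(sum((a - b) ** 2 / s for a, b, s in zip(y, x, cov)))
    diff = np.asarray(y) - np.asarray(x)
    return float(diff @ np.linalg.inv(cov) @ diff)


def _bf_pca(centroids, k):
    mean = centroids.mean(axis=0)
    centered = centroids - mean
    cov = centered.T @ centered
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:k]
    return mean, eigvec[:, order]


def brute_force_predict(training_runs, spec, froi, test_run):
    mats = [_bf_class_matrix(r)[:, froi] for r in training_runs]
    test = test_run.data[:, froi]
    n_classes = mats[0].shape[0]

    if spec.scheme == "nearest_neighbor":
        preds = []
        for y in test:
            best = (np.inf, None)
            for mat in mats:
                for c in range(n_classes):
                    d = _bf_dist(y, mat[c], spec.metric)
                    if d < best[0] or (d == best[0] and c < best[1]):
                        best = (d, c)
            preds.append(best[1])
        return np.array(preds)

    centroids = sum(mats) / len(mats)
    if spec.n_pcs is not None:
        k = min(spec.n_pcs, n_classes - 1, len(froi))
        mean, basis = _bf_pca(centroids, k)
        centroids = (centroids - mean) @ basis
        mats = [(m - mean) @ basis for m in mats]
        test = (test - mean) @ basis
    cov = None
    if spec.metric in ("normalized_euclidean", "mahalanobis"):
        residuals = np.concatenate([m - centroids for m in mats])
        full = residuals.T @ residuals / residuals.shape[0]
        ridge = RIDGE * np.trace(full) / full.shape[0]
        if spec.metric == "normalized_euclidean":
            cov = np.diag(full) + ridge
        else:
            cov = full + ridge * np.eye(full.shape[0])
    preds = []
    for y in test:
        dists = [_bf_dist(y, centroids[c], spec.metric, cov) for c in range(n_classes)]
        preds.append(int(np.argmin(dists)))
    return np.array(preds)


ALL_SPECS = ["NNC", "NNE", "NMC", "NME", "GNB", "NMC2", "NME2", "GNB2", "LDA2"]


@pytest.mark.parametrize("name", ALL_SPECS)
def test_brute_force_oracle_agreement(name, toy_runs):
    """Every spec's predictions equal a naive independent reimplementation's
    on a 3-class, 5-voxel, 3-run toy problem."""
    spec = ClassifierSpec.from_name(name)
    froi = np.arange(5)
    model = fit(toy_runs[:2], spec, froi)
    got = predict(model, toy_runs[2]).predicted
    expected = brute_force_predict(toy_runs[:2], spec, froi, toy_runs[2])
    np.testing.assert_array_equal(got, expected)
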