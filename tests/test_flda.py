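import numpy as np
import pytest

from subband_flda import FisherLDA, fisher_criterion, flda_fit, scatter_matrices
from subband_flda.errors import (
    ArgumentError,
    DegenerateClassError,
    ShapeError,
    SingularityError,
)
from subband_flda.signal_io import ASD, NORMAL

from conftest import make_two_gaussians


def brute_force_scatter(X, y):
    """Independent double-loop oracle for the scatter matrices."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    d = X.shape[1]
    mu = X.mean(axis=0)
    S_w = np.zeros((d, d))
    S_b = np.zeros((d, d))
    for c in np.unique(y):
        Xc = X[y == c]
        mu_c = Xc.mean(axis=0)
        for row in Xc:
            diff = (row - mu_c)[:, None]
            S_w += diff @ diff.T
        db = (mu_c - mu)[:, None]
        S_b += len(Xc) * (db @ db.T)
    return S_w, S_b


class TestScatterMatrices:
    def test_matches_brute_force_oracle(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=200, d=2)
        S_w, S_b = scatter_matrices(X, y)
        S_w_ref, S_b_ref = brute_force_scatter(X, y)
        np.testing.assert_allclose(S_w, S_w_ref, atol=1e-10 * np.abs(S_w_ref).max())
        np.testing.assert_allclose(S_b, S_b_ref, atol=1e-10 * max(np.abs(S_b_ref).max(), 1))

    def test_identical_class_means_zero_between_scatter(self, rng):
        base = rng.standard_normal((40, 3))
        X = np.vstack([base, base])  # identical clouds -> identical class means
        y = np.array([ASD] * 40 + [NORMAL] * 40, dtype=object)
        _, S_b = scatter_matrices(X, y)
        assert np.max(np.abs(S_b)) < 1e-10

    def test_repeated_points_zero_within_scatter(self):
        X = np.vstack([np.tile([1.0, 2.0], (3, 1)), np.tile([3.0, -1.0], (3, 1))])
        y = np.array([ASD] * 3 + [NORMAL] * 3, dtype=object)
        S_w, _ = scatter_matrices(X, y, allow_degenerate=True)
        assert np.all(S_w == 0)

    def test_small_class_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([ASD, NORMAL, NORMAL], dtype=object)
        with pytest.raises(DegenerateClassError):
            scatter_matrices(X, y)

    def test_positive_semidefinite(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=50, d=4)
        for S in scatter_matrices(X, y):
            eigs = np.linalg.eigvalsh(S)
            assert eigs.min() > -1e-10


class TestFisherCriterion:
    def test_zero_between_scatter_gives_zero(self, rng):
        S_w = np.eye(3)
        S_b = np.zeros((3, 3))
        w = rng.standard_normal(3)
        assert fisher_criterion(w, S_w, S_b) == 0.0

    def test_scale_invariance(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=100, d=3, delta=(2.0, 1.0, 0.0))
        S_w, S_b = scatter_matrices(X, y)
        w = rng.standard_normal(3)
        assert fisher_criterion(2 * w, S_w, S_b) == pytest.approx(
            fisher_criterion(w, S_w, S_b)
        )

    def test_null_direction_rejected(self):
        S_w = np.diag([1.0, 0.0])
        with pytest.raises(SingularityError):
            fisher_criterion(np.array([0.0, 1.0]), S_w, np.eye(2))


class TestFit:
    def test_direction_on_separated_isotropic_clouds(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=500, d=2, delta=(4.0, 0.0))
        res = FisherLDA(X, y, normalize=False).fit(ridge=0.0)
        w = res.W[:, 0]
        cos = abs(w @ np.array([1.0, 0.0])) / np.linalg.norm(w)
        assert cos > 0.99

    def test_matches_closed_form_binary_solution(self, rng):
        """Eigen solution equals S_w^{-1}(mu1 - mu0) up to scale (cos > 1 - 1e-10)."""
        for trial in range(5):
            X, y = make_two_gaussians(rng, n_per_class=80, d=5,
                                      delta=(2.0, -1.0, 0.5, 0.0, 1.0))
            res = FisherLDA(X, y, normalize=False).fit(ridge=0.0)
            S_w, _ = scatter_matrices(X, y)
            mu1 = X[y == ASD].mean(axis=0)
            mu0 = X[y == NORMAL].mean(axis=0)
            w_ref = np.linalg.solve(S_w, mu1 - mu0)
            w = res.W[:, 0]
            cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
            assert cos > 1 - 1e-10

    def test_generalized_eigenpair_residual(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=100, d=4, delta=(3.0, 1.0, 0.0, -2.0))
        res = FisherLDA(X, y, normalize=False).fit(ridge=0.0)
        S_w, S_b = scatter_matrices(X, y)
        w = res.W[:, 0]
        lam = res.eigenvalues[0]
        residual = np.linalg.norm(S_b @ w - lam * (S_w @ w))
        assert residual < 1e-8 * max(1.0, np.abs(S_b).max())

    def test_criterion_beats_random_directions(self, rng):
        """Fitted J(w) >= J over 1e5 random unit directions on a 3-D toy."""
        X, y = make_two_gaussians(rng, n_per_class=150, d=3, delta=(2.0, 1.0, -1.0))
        res = FisherLDA(X, y, normalize=False).fit(ridge=0.0)
        S_w, S_b = scatter_matrices(X, y)
        J_fit = fisher_criterion(res.W[:, 0], S_w, S_b)
        V = rng.standard_normal((100_000, 3))
        num = np.einsum("ij,jk,ik->i", V, S_b, V)
        den = np.einsum("ij,jk,ik->i", V, S_w, V)
        assert J_fit >= np.max(num / den) - 1e-12

    def test_matches_sklearn_lda_direction(self, rng):
        """Independent cross-check against scikit-learn's LDA coefficients."""
        sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = make_two_gaussians(rng, n_per_class=200, d=4, delta=(2.0, 0.0, 1.0, -1.0))
        res = FisherLDA(X, y, normalize=False).fit(ridge=0.0)
        clf = sklearn_lda.LinearDiscriminantAnalysis(solver="eigen")
        clf.fit(X, y.astype(str))
        w_ref = clf.coef_[0]
        w = res.W[:, 0]
        cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
        assert cos > 1 - 1e-6

    def test_singular_without_ridge_raises_with_ridge_works(self, rng):
        base = rng.standard_normal((60, 2))
        X = np.column_stack([base[:, 0], base[:, 0], base[:, 1]])  # rank-deficient
        y = np.array([ASD] * 30 + [NORMAL] * 30, dtype=object)
        y_shift = X[:, 2] > 0
        X[y_shift] += 0.5
        with pytest.raises(SingularityError):
            FisherLDA(X, y, normalize=False).fit(ridge=0.0)
        res = FisherLDA(X, y, normalize=False).fit(ridge=1e-6)
        assert np.isfinite(res.W).all()

    def test_unit_norm_and_orientation(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=100, d=3, delta=(3.0, 0.0, 0.0))
        res = FisherLDA(X, y).fit()
        np.testing.assert_allclose(np.linalg.norm(res.W, axis=0), 1.0, atol=1e-12)
        assert res.class_means_projected[ASD][0] >= res.class_means_projected[NORMAL][0]
        assert (
            res.class_means_projected[NORMAL][0]
            <= res.threshold
            <= res.class_means_projected[ASD][0]
        )


class TestPredict:
    def test_training_means_classified_correctly(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=200, d=2, delta=(4.0, 1.0))
        res = FisherLDA(X, y).fit()
        mu_pos = X[y == ASD].mean(axis=0)
        mu_neg = X[y == NORMAL].mean(axis=0)
        assert res.predict(np.vstack([mu_pos, mu_neg])).tolist() == [ASD, NORMAL]

    def test_tie_goes_to_positive_class(self):
        """A score exactly at the threshold is assigned the positive class."""
        from subband_flda import FisherLDAResults
        from subband_flda.features import NormalizationStats
        res = FisherLDAResults(
            W=np.array([[1.0], [0.0]]),
            eigenvalues=np.array([1.0]),
            classes=(ASD, NORMAL),
            class_means_projected={ASD: np.array([2.0]), NORMAL: np.array([1.0])},
            class_counts={ASD: 10, NORMAL: 10},
            threshold=1.5,
            class_order=(NORMAL, ASD),
            norm_stats=NormalizationStats(np.zeros(2), np.ones(2), 20),
            ridge=0.0,
            n_obs=20,
        )
        preds = res.predict(np.array([[1.5, 0.0], [1.5 - 1e-9, 0.0], [1.5 + 1e-9, 0.0]]))
        assert preds.tolist() == [ASD, NORMAL, ASD]

    def test_equivalent_to_nearest_projected_mean(self, rng):
        """With equal spherical covariances the midpoint rule is nearest-mean."""
        X, y = make_two_gaussians(rng, n_per_class=300, d=3, delta=(2.0, 2.0, 0.0))
        res = FisherLDA(X, y).fit()
        X_test, _ = make_two_gaussians(rng, n_per_class=100, d=3, delta=(2.0, 2.0, 0.0))
        scores = res.project(X_test)[:, 0]
        m_pos = res.class_means_projected[ASD][0]
        m_neg = res.class_means_projected[NORMAL][0]
        nearest = np.where(
            np.abs(scores - m_pos) <= np.abs(scores - m_neg), ASD, NORMAL
        )
        np.testing.assert_array_equal(res.predict(X_test), nearest)

    def test_predictions_invariant_to_feature_scaling(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=150, d=3, delta=(2.0, -1.0, 0.5))
        X_test = rng.standard_normal((50, 3))
        base = FisherLDA(X, y).fit().predict(X_test)
        for c in (10.0, 0.01):
            scaled = FisherLDA(c * X, y).fit().predict(c * X_test)
            np.testing.assert_array_equal(scaled, base)

    def test_scores_absorb_constant_shift_of_fitted_rows(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=100, d=3, delta=(2.0, 0.0, 1.0))
        shift = np.array([5.0, -3.0, 2.0])
        s0 = FisherLDA(X, y).fit().project(X)
        s1 = FisherLDA(X + shift, y).fit().project(X + shift)
        np.testing.assert_allclose(s0, s1, atol=1e-8)

    def test_zero_row_after_normalization_scores_zero(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=100, d=2, delta=(3.0, 0.0))
        res = FisherLDA(X, y).fit()
        x = res.norm_stats.mean  # normalizes to the zero vector
        assert res.project(x[None, :])[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=50, d=3)
        res = FisherLDA(X, y).fit()
        with pytest.raises(ShapeError):
            res.predict(rng.standard_normal((5, 4)))


class TestMultiClassAndRecovery:
    def test_three_class_projection_has_two_components(self, rng):
        X = np.vstack([
            rng.standard_normal((50, 4)),
            rng.standard_normal((50, 4)) + [4, 0, 0, 0],
            rng.standard_normal((50, 4)) + [0, 4, 0, 0],
        ])
        y = np.array(["a"] * 50 + ["b"] * 50 + ["c"] * 50, dtype=object)
        res = FisherLDA(X, y, positive_label="a", negative_label="b").fit()
        assert res.n_components == 2
        assert res.threshold is None
        preds = res.predict(X)
        assert (preds == y).mean() > 0.85

    def test_direction_recovery_improves_with_sample_size(self):
        """Angle to the planted discriminant direction shrinks as n grows."""
        planted = np.array([1.0, 2.0, -1.0]) / np.sqrt(6.0)
        angles = []
        for i, n in enumerate([50, 500, 5000]):
            rng = np.random.default_rng(1000 + i)
            X = rng.standard_normal((2 * n, 3))
            y = np.array([ASD] * n + [NORMAL] * n, dtype=object)
            X[:n] += 1.0 * planted
            res = FisherLDA(X, y, normalize=False).fit()
            w = res.W[:, 0]
            cos = abs(w @ planted)
            angles.append(np.arccos(min(cos, 1.0)))
        assert angles[0] > angles[1] > angles[2]
        assert angles[2] < 0.05

    def test_functional_wrapper_and_serialization_roundtrip(self, rng, tmp_path):
        X, y = make_two_gaussians(rng, n_per_class=80, d=3, delta=(2.0, 1.0, 0.0))
        res = flda_fit(X, y)
        path = tmp_path / "model.json"
        res.to_json(path)
        from subband_flda import FisherLDAResults
        back = FisherLDAResults.from_json(path)
        np.testing.assert_allclose(back.W, res.W)
        assert back.threshold == pytest.approx(res.threshold)
        X_test = rng.standard_normal((20, 3))
        np.testing.assert_array_equal(back.predict(X_test), res.predict(X_test))

    def test_summary_mentions_key_quantities(self, rng):
        X, y = make_two_gaussians(rng, n_per_class=60, d=2)
        text = FisherLDA(X, y).fit().summary()
        for token in ("threshold", "ASD", "NORMAL", "components", "ridge"):
            assert token in text

    def test_nonfinite_features_rejected(self):
        X = np.array([[np.nan, 1.0], [0.0, 1.0], [2.0, 3.0], [1.0, 2.0]])
        y = np.array([ASD, ASD, NORMAL, NORMAL], dtype=object)
        with pytest.raises(ArgumentError):
            FisherLDA(X, y)
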