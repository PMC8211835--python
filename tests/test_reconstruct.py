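import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glimap import (
    InvalidDataError,
    MappingModel,
    ParameterError,
    WeightConfig,
    compute_weights,
    e_step,
    mahalanobis_distances,
    map_reference,
    reconstruct_expression,
    weight_sensitivity,
)


def make_model(pi, a, b, sigma2, R):
    model = MappingModel(np.asarray(pi, float), np.asarray(a, float),
                         np.asarray(b, float), np.asarray(sigma2, float),
                         np.empty((len(a), len(pi))))
    model.mu = map_reference(model, np.asarray(R, float))
    return model


class TestMahalanobisDistances:
    def test_unit_variance_reduces_to_euclidean(self, rng):
        from scipy.spatial.distance import cdist

        X = rng.normal(size=(3, 6))
        mu = rng.normal(size=(3, 4))
        D = mahalanobis_distances(X, mu, np.ones(3))
        np.testing.assert_allclose(D, cdist(X.T, mu.T), atol=1e-10)

    def test_zero_at_the_mean_and_symmetry(self, rng):
        mu = rng.normal(size=(3, 4))
        s2 = rng.uniform(0.5, 2, 3)
        D = mahalanobis_distances(mu, mu, s2)
        np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-7)
        np.testing.assert_allclose(D, D.T, atol=1e-10)

    def test_hand_example(self):
        D = mahalanobis_distances(np.array([[1.0], [2.0]]),
                                  np.array([[0.0], [0.0]]),
                                  np.array([1.0, 4.0]))
        assert D[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            mahalanobis_distances(np.zeros((2, 1)), np.zeros((2, 1)),
                                  np.array([1.0, 0.0]))


class TestComputeWeights:
    def test_posterior_identity_with_half_alpha(self, rng):
        # alpha = 1/2, beta = 0, uniform pi: weights are the E-step posterior
        M, N, K = 3, 7, 5
        X = rng.normal(size=(M, N))
        R = rng.normal(size=(M, K))
        model = make_model(np.full(K, 1.0 / K), rng.uniform(0.5, 2, M),
                           rng.normal(size=M), rng.uniform(0.5, 2, M), R)
        D = mahalanobis_distances(X, model.mu, model.sigma2)
        w = compute_weights(D, model.pi, WeightConfig(0.5, 0.0))
        np.testing.assert_allclose(w, e_step(X, model), atol=1e-10)

    def test_sharp_alpha_limit_is_argmin_one_hot(self, rng):
        D = rng.uniform(0.5, 5.0, size=(6, 4))
        w = compute_weights(D, np.full(4, 0.25), WeightConfig(1e6, 0.0))
        np.testing.assert_allclose(
            w, np.eye(4)[D.argmin(axis=1)], atol=1e-12)

    def test_exact_distance_ties_share_weight(self):
        D = np.array([[1.0, 1.0, 3.0]])
        w = compute_weights(D, np.full(3, 1 / 3), WeightConfig(1e6, 0.0))
        np.testing.assert_allclose(w, [[0.5, 0.5, 0.0]], atol=1e-12)

    def test_hand_scalar_example(self):
        D = np.array([[1.0, 2.0]])
        w = compute_weights(D, np.array([0.5, 0.5]), WeightConfig(0.0, 1.0))
        np.testing.assert_allclose(w, [[0.73105858, 0.26894142]], atol=1e-7)

    def test_extreme_distances_never_underflow_rows(self):
        D = np.array([[1e4, 2e4], [1e-3, 1e5]])
        w = compute_weights(D, np.array([0.5, 0.5]), WeightConfig(1.0, 0.0))
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_nan_distance_rejected(self):
        with pytest.raises(InvalidDataError):
            compute_weights(np.array([[np.nan, 1.0]]), np.array([0.5, 0.5]),
                            WeightConfig(0.5, 0.0))

    @given(st.floats(0, 8), st.floats(0, 8), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_rows_sum_to_one(self, alpha, beta, seed):
        rng = np.random.default_rng(seed)
        D = rng.uniform(0, 30, size=(5, 6))
        with np.errstate(all="ignore"), pytest.warns(UserWarning) \
                if (alpha == 0 and beta == 0) else np.errstate(all="ignore"):
            w = compute_weights(D, np.full(6, 1 / 6),
                                WeightConfig(alpha, beta))
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


class TestReconstructExpression:
    def test_uniform_weights_give_global_mean(self, rng):
        Y = rng.normal(size=(3, 5))
        w = np.full((5, 2), 0.5)
        ybar = reconstruct_expression(Y, w)
        np.testing.assert_allclose(ybar, np.tile(Y.mean(axis=1), (2, 1)))

    def test_one_hot_column_selects_that_cell(self, rng):
        Y = rng.normal(size=(3, 4))
        w = np.zeros((4, 2))
        w[2, 0] = 1.0
        w[1, 1] = 0.25
        ybar = reconstruct_expression(Y, w)
        np.testing.assert_allclose(ybar[0], Y[:, 2])
        np.testing.assert_allclose(ybar[1], Y[:, 1])

    def test_matches_double_loop_oracle(self, rng):
        Y = rng.normal(size=(3, 4))
        w = rng.uniform(0.1, 1, size=(4, 2))
        ybar = reconstruct_expression(Y, w)
        for k in range(2):
            for g in range(3):
                expected = sum(w[n, k] * Y[g, n] for n in range(4)) / w[:, k].sum()
                assert ybar[k, g] == pytest.approx(expected)

    def test_column_rescaling_invariance(self, rng):
        Y = rng.normal(size=(2, 6))
        w = rng.uniform(0.1, 1, size=(6, 3))
        w2 = w * np.array([1.0, 7.5, 0.01])
        np.testing.assert_allclose(reconstruct_expression(Y, w),
                                   reconstruct_expression(Y, w2), atol=1e-12)

    def test_zero_weight_column_falls_back_to_global_mean(self, rng):
        Y = rng.normal(size=(2, 4))
        w = np.zeros((4, 2))
        w[:, 0] = 0.25
        with pytest.warns(UserWarning, match="zero total weight"):
            ybar = reconstruct_expression(Y, w)
        np.testing.assert_allclose(ybar[1], Y.mean(axis=1))


class TestWeightSensitivity:
    def _instance(self, rng, alpha, beta, sigma2=None):
        # competing position matches x in the probed coordinate, so the
        # closed form is the exact softmax derivative there
        M, K = 3, 2
        x = rng.normal(size=M)
        mu = rng.normal(size=(M, K))
        probe = 1
        mu[probe, 1] = x[probe]
        X = x[:, None]
        s2 = np.ones(M) if sigma2 is None else sigma2
        model = MappingModel(np.array([0.5, 0.5]), np.ones(M), np.zeros(M),
                             s2, mu)
        D = mahalanobis_distances(X, mu, model.sigma2)
        w = compute_weights(D, model.pi, WeightConfig(alpha, beta))
        return X, model, w, probe

    @pytest.mark.parametrize("alpha, beta", [(0.5, 0.0), (1.0, 2.0),
                                             (0.0, 1.5)])
    def test_matches_central_finite_differences(self, rng, alpha, beta):
        X, model, w, probe = self._instance(rng, alpha, beta)
        cfg = WeightConfig(alpha, beta)
        grad = weight_sensitivity(X, model, w, cfg, 0, 0)
        h = 1e-6
        Xp, Xm = X.copy(), X.copy()
        Xp[probe, 0] += h
        Xm[probe, 0] -= h
        fd = (
            compute_weights(mahalanobis_distances(Xp, model.mu, model.sigma2),
                            model.pi, cfg)[0, 0]
            - compute_weights(mahalanobis_distances(Xm, model.mu, model.sigma2),
                              model.pi, cfg)[0, 0]
        ) / (2 * h)
        assert grad[probe] == pytest.approx(fd, rel=1e-4)

    def test_gradient_vanishes_where_x_equals_mu(self, rng):
        X, model, w, _ = self._instance(rng, 0.5, 0.0)
        model.mu[0, 0] = X[0, 0]
        grad = weight_sensitivity(X, model, w, WeightConfig(0.5, 0.0), 0, 0)
        assert grad[0] == 0.0

    def test_inverse_variance_proportionality(self, rng):
        # within one gradient, components are proportional to (x - mu) / sigma^2
        X, model, w, _ = self._instance(
            rng, 0.5, 0.0, sigma2=np.array([1.0, 2.0, 4.0]))
        grad = weight_sensitivity(X, model, w, WeightConfig(0.5, 0.0), 0, 0)
        ratio = (X[:, 0] - model.mu[:, 0]) / model.sigma2
        np.testing.assert_allclose(grad / ratio, grad[0] / ratio[0],
                                   rtol=1e-10)

    def test_zero_distance_returns_nan_sentinel(self):
        mu = np.zeros((2, 1))
        model = MappingModel(np.array([1.0]), np.ones(2), np.zeros(2),
                             np.ones(2), mu)
        X = np.zeros((2, 1))
        w = np.ones((1, 1))
        with pytest.warns(UserWarning, match="undefined"):
            grad = weight_sensitivity(X, model, w, WeightConfig(0.5, 0.0),
                                      0, 0)
        assert np.isnan(grad).all()
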