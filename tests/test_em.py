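import numpy as np
import pytest

from glimap import (
    MappingModel,
    e_step,
    fit_em,
    init_params,
    log_likelihood,
    m_step,
    map_reference,
)
from glimap.em import q_function


def make_model(pi, a, b, sigma2, R):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    model = MappingModel(np.asarray(pi, float), a, b, np.asarray(sigma2, float),
                         np.empty((len(a), len(pi))))
    model.mu = map_reference(model, np.asarray(R, float))
    return model


def direct_density(x, mu, sigma2):
    """Multivariate diagonal Gaussian density without any log-space tricks."""
    M = len(x)
    norm = (2 * np.pi) ** (-M / 2) * np.prod(sigma2) ** -0.5
    return norm * np.exp(-0.5 * np.sum((x - mu) ** 2 / sigma2))


class TestInitParams:
    def test_identical_moments_give_identity_map(self, rng):
        X = rng.normal(size=(3, 40))
        model = init_params(X, X.copy())
        np.testing.assert_allclose(model.a, np.ones(3), atol=1e-12)
        np.testing.assert_allclose(model.b, np.zeros(3), atol=1e-12)

    def test_hand_moments(self):
        # x values (0, 2): mean 1, population sd 1; r values (0, 1): mean .5, sd .5
        X = np.array([[0.0, 2.0]])
        R = np.array([[0.0, 1.0]])
        model = init_params(X, R)
        assert model.a[0] == pytest.approx(2.0)
        assert model.b[0] == pytest.approx(0.0)

    def test_sigma2_is_population_variance_per_row(self, rng):
        X = rng.normal(size=(4, 25))
        R = rng.normal(size=(4, 9))
        model = init_params(X, R)
        for i in range(4):
            expected = sum((v - X[i].mean()) ** 2 for v in X[i]) / 25
            assert model.sigma2[i] == pytest.approx(expected)

    def test_zero_variance_reference_metagene(self, rng):
        X = rng.normal(size=(2, 10))
        R = np.vstack([np.ones(5), rng.normal(size=5)])
        with pytest.warns(UserWarning, match="zero-variance"):
            model = init_params(X, R)
        assert model.a[0] == 0.0
        assert model.b[0] == pytest.approx(X[0].mean())


class TestLogLikelihood:
    def test_single_component_at_its_mean(self):
        M = 3
        R = np.zeros((M, 1))
        model = make_model([1.0], np.ones(M), np.zeros(M), np.ones(M), R)
        X = np.zeros((M, 1))
        assert log_likelihood(X, model) == pytest.approx(-M / 2 * np.log(2 * np.pi))

    def test_matches_direct_density_oracle(self, rng):
        N, K, M = 5, 3, 2
        X = rng.normal(size=(M, N))
        R = rng.normal(size=(M, K))
        model = make_model(rng.dirichlet(np.ones(K)), rng.uniform(0.5, 2, M),
                           rng.normal(size=M), rng.uniform(0.5, 2, M), R)
        expected = 0.0
        for n in range(N):
            expected += np.log(sum(
                model.pi[k] * direct_density(X[:, n], model.mu[:, k],
                                             model.sigma2)
                for k in range(K)))
        assert log_likelihood(X, model) == pytest.approx(expected, abs=1e-9)

    def test_duplicate_component_with_split_weight(self, rng):
        M, K = 2, 3
        X = rng.normal(size=(M, 6))
        R = rng.normal(size=(M, K))
        model = make_model([0.5, 0.3, 0.2], [1.0, 1.2], [0.0, -0.1],
                           [1.0, 0.8], R)
        R2 = np.hstack([R, R[:, [0]]])
        model2 = make_model([0.25, 0.3, 0.2, 0.25], model.a, model.b,
                            model.sigma2, R2)
        assert log_likelihood(X, model) == pytest.approx(
            log_likelihood(X, model2), abs=1e-10)


class TestEStep:
    def test_single_component(self, rng):
        X = rng.normal(size=(2, 5))
        model = make_model([1.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0],
                           np.zeros((2, 1)))
        np.testing.assert_allclose(e_step(X, model), np.ones((5, 1)))

    def test_equidistant_point_splits_evenly(self):
        R = np.array([[-1.0, 1.0]])
        model = make_model([0.5, 0.5], [1.0], [0.0], [1.0], R)
        gamma = e_step(np.array([[0.0]]), model)
        np.testing.assert_allclose(gamma, [[0.5, 0.5]], atol=1e-12)

    def test_matches_direct_bayes_oracle(self, rng):
        N, K, M = 4, 3, 2
        X = rng.normal(size=(M, N))
        R = rng.normal(size=(M, K))
        model = make_model(rng.dirichlet(np.ones(K)), rng.uniform(0.5, 2, M),
                           rng.normal(size=M), rng.uniform(0.5, 2, M), R)
        gamma = e_step(X, model)
        for n in range(N):
            dens = np.array([model.pi[k] * direct_density(
                X[:, n], model.mu[:, k], model.sigma2) for k in range(K)])
            np.testing.assert_allclose(gamma[n], dens / dens.sum(), atol=1e-10)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_one_hot_responsibilities_reproduce_ols(self, rng):
        N, K, M = 20, 8, 3
        X = rng.normal(size=(M, N))
        R = rng.normal(size=(M, K))
        assign = rng.integers(0, K, size=N)
        gamma = np.zeros((N, K))
        gamma[np.arange(N), assign] = 1.0
        model = m_step(X, R, gamma, prev=init_params(X, R))
        for i in range(M):
            slope, intercept = np.polyfit(R[i, assign], X[i], 1)
            assert model.a[i] == pytest.approx(slope, abs=1e-8)
            assert model.b[i] == pytest.approx(intercept, abs=1e-8)
            resid = X[i] - slope * R[i, assign] - intercept
            assert model.sigma2[i] == pytest.approx(np.mean(resid**2), abs=1e-8)

    def test_update_maximizes_q(self, rng):
        N, K, M = 12, 5, 2
        X = rng.normal(size=(M, N))
        R = rng.normal(size=(M, K))
        gamma = rng.dirichlet(np.ones(K), size=N)
        model = m_step(X, R, gamma, prev=init_params(X, R))
        q0 = q_function(X, R, gamma, model)
        for attr in ("a", "b", "sigma2"):
            for i in range(M):
                for eps in (-1e-4, 1e-4):
                    perturbed = MappingModel(model.pi, model.a.copy(),
                                             model.b.copy(),
                                             model.sigma2.copy(), model.mu)
                    getattr(perturbed, attr)[i] += eps
                    perturbed.mu = map_reference(perturbed, R)
                    assert q_function(X, R, gamma, perturbed) <= q0 + 1e-10

    def test_uniform_responsibilities_give_uniform_pi(self, rng):
        N, K, M = 10, 4, 2
        X = rng.normal(size=(M, N))
        R = rng.normal(size=(M, K))
        gamma = np.full((N, K), 1.0 / K)
        model = m_step(X, R, gamma, pi_mode="updated",
                       prev=init_params(X, R, "updated"))
        np.testing.assert_allclose(model.pi, np.full(K, 0.25), atol=1e-12)


class TestFitEm:
    def test_loglik_nondecreasing(self, small_truth):
        D = small_truth.ref.expr.n_genes
        X = small_truth.sc.values[:D]
        R = small_truth.ref.expr.values
        _, trace = fit_em(X, R, max_iter=50)
        diffs = np.diff(trace.loglik_per_iter)
        assert np.all(diffs >= -1e-8)

    def test_noise_free_data_collapses_to_one_hot(self, noisefree_truth):
        D = noisefree_truth.ref.expr.n_genes
        X = noisefree_truth.sc.values[:D]
        R = noisefree_truth.ref.expr.values
        model, _ = fit_em(X, R, max_iter=200, sigma2_floor_scale=1e-10)
        gamma = e_step(X, model)
        hits = gamma[np.arange(X.shape[1]), noisefree_truth.true_origin]
        assert np.median(hits) > 0.999

    def test_permutation_equivariance(self, rng, small_truth):
        D = small_truth.ref.expr.n_genes
        X = small_truth.sc.values[:D, :80]
        R = small_truth.ref.expr.values
        perm = rng.permutation(X.shape[1])
        model1, _ = fit_em(X, R, max_iter=30)
        model2, _ = fit_em(X[:, perm], R, max_iter=30)
        np.testing.assert_allclose(model1.a, model2.a, rtol=1e-9)
        np.testing.assert_allclose(model1.b, model2.b, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(e_step(X, model1)[perm],
                                   e_step(X[:, perm], model2), atol=1e-9)

    def test_fixed_pi_modes_never_touch_pi(self, small_truth):
        D = small_truth.ref.expr.n_genes
        X = small_truth.sc.values[:D, :100]
        R = small_truth.ref.expr.values
        K = R.shape[1]
        model, _ = fit_em(X, R, pi_mode="fixed_uniform", max_iter=25)
        np.testing.assert_array_equal(model.pi, np.full(K, 1.0 / K))
        mass = np.linspace(1, 2, K)
        model2, _ = fit_em(X, R, pi_mode="fixed_mass", prior_mass=mass,
                           max_iter=25)
        np.testing.assert_allclose(model2.pi, mass / mass.sum())

    def test_recovery_error_shrinks_with_sample_size(self):
        from glimap import generate_cells, generate_tissue, recovery_report

        ref = generate_tissue(K=36, n_landmarks=10, seed=11)
        errors = []
        for N in (100, 400, 1600):
            med = []
            for seed in range(3):
                truth = generate_cells(ref, N, seed=100 + seed)
                D = truth.ref.expr.n_genes
                model, _ = fit_em(truth.sc.values[:D], ref.expr.values,
                                  max_iter=100)
                rep = recovery_report(truth, model)
                med.append(rep.rel_err_a + rep.rel_err_b)
            errors.append(np.median(med))
        assert errors[2] < errors[0]


class TestMapReference:
    def test_identity_and_constant_maps(self, rng):
        R = rng.normal(size=(3, 4))
        ident = make_model(np.full(4, 0.25), [1, 1, 1], [0, 0, 0], [1, 1, 1], R)
        np.testing.assert_array_equal(map_reference(ident, R), R)
        flat = make_model(np.full(4, 0.25), [0, 0, 0], [2, -1, 3], [1, 1, 1], R)
        np.testing.assert_allclose(map_reference(flat, R),
                                   np.tile([[2.0], [-1.0], [3.0]], (1, 4)))

    def test_matches_entry_loop_oracle(self, rng):
        M, K = 3, 4
        R = rng.normal(size=(M, K))
        model = make_model(np.full(K, 0.25), rng.normal(size=M),
                           rng.normal(size=M), np.ones(M), R)
        mu = map_reference(model, R)
        for i in range(M):
            for k in range(K):
                assert mu[i, k] == pytest.approx(
                    model.a[i] * R[i, k] + model.b[i])

    def test_mu_invariant_after_fit(self, small_truth):
        D = small_truth.ref.expr.n_genes
        X = small_truth.sc.values[:D, :60]
        R = small_truth.ref.expr.values
        model, _ = fit_em(X, R, max_iter=20)
        np.testing.assert_allclose(model.mu, map_reference(model, R),
                                   atol=1e-12)
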