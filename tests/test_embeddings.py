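import numpy as np
import pytest

from cse import (EmbeddingEstimate, KernelSpec, counterfactual_embedding,
                 evaluate_embedding, fit_cme_coefficients, gram, rkhs_distance)
from cse.censoring import ipcw_weights, reverse_kaplan_meier


def weighted_ridge_risk(B, K, L, W, eps):
    """Empirical risk of the vector-valued regression with coefficient matrix B.

    F = sum_j Gamma(., X_j) c_j with c_j = sum_s B[j, s] l(T_s, .);
    R = (1/n) sum_i W_i ||l(T_i,.) - F(X_i)||^2 + eps ||F||^2.
    """
    n = K.shape[0]
    KBL = K @ B @ L
    fit = np.diag(L) - 2 * np.diag(KBL) + np.diag(KBL @ B.T @ K)
    return float((W * fit).sum() / n + eps * np.trace(K @ B @ L @ B.T))


def risk_gradient(B, K, L, W, eps):
    n = K.shape[0]
    return (2 / n) * K @ (np.diag(W) @ K @ B + n * eps * B - np.diag(W)) @ L


def minimize_risk_numerically(rng, K, L, W, eps):
    """Generic minimizer of the (quadratic) weighted ridge risk.

    Solves the stationarity equations grad R = 0 as a least-squares system
    in vec(B): (K W K + n eps K) B L = K W L, written with a Kronecker
    product and handed to a minimum-norm solver.  Derived only from the
    risk's gradient, not from the closed-form inversion identity; the
    pseudo-inverse handles the flat directions of near-singular Grams.
    """
    n = K.shape[0]
    A = K @ (W[:, None] * K) + n * eps * K
    rhs = (K @ (W[:, None] * L)).ravel()
    x, *_ = np.linalg.lstsq(np.kron(A, L), rhs, rcond=None)
    B = x.reshape(n, n)
    # sanity: stationary point found by the generic route is a minimizer
    assert weighted_ridge_risk(B, K, L, W, eps) <= weighted_ridge_risk(
        np.zeros((n, n)), K, L, W, eps) + 1e-12
    return B


def regressor_distance(B1, B2, K, L):
    """RKHS norm of the difference of the two fitted regressors."""
    D = B1 - B2
    return float(np.sqrt(max(np.trace(K @ D @ L @ D.T), 0.0)))


def random_instance(rng, n):
    t = rng.exponential(1.0, n)
    e = (rng.random(n) < 0.7).astype(float)
    if e.sum() == 0:
        e[0] = 1.0
    X = rng.normal(size=(n, 2))
    W = ipcw_weights(t, e, reverse_kaplan_meier(t, e))
    K = gram(X, X, KernelSpec(1.0))
    L = gram(t, t, KernelSpec(1.0))
    return t, e, X, W, K, L


class TestClosedFormMinimizer:
    def test_scalar_system(self):
        # n=1, W=1: (1 + eps) c = h  ->  c = 1/(1+eps)
        solver = fit_cme_coefficients(np.array([[0.3]]), KernelSpec(1.0), 0.25, [1.0])
        assert solver.solve(np.array([1.0]))[0] == pytest.approx(1 / 1.25)

    def test_uncensored_reduces_to_standard_ridge(self, rng):
        n = 12
        X = rng.normal(size=(n, 2))
        K = gram(X, X, KernelSpec(1.0))
        eps = 0.05
        b = rng.normal(size=n)
        solver = fit_cme_coefficients(X, KernelSpec(1.0), eps, np.ones(n))
        expected = np.linalg.solve(K + n * eps * np.eye(n), b)
        assert np.allclose(solver.solve(b), expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_generic_numerical_minimizer(self, seed):
        # independent oracle: BFGS minimization of the weighted ridge risk
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        t, e, X, W, K, L = random_instance(rng, n)
        eps = 0.1
        B_closed = np.linalg.solve(np.diag(W) @ K + n * eps * np.eye(n), np.diag(W))
        B_num = minimize_risk_numerically(rng, K, L, W, eps)
        assert regressor_distance(B_closed, B_num, K, L) <= 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_perturbations_do_not_decrease_risk(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 7))
        t, e, X, W, K, L = random_instance(rng, n)
        eps = 0.1
        B = np.linalg.solve(np.diag(W) @ K + n * eps * np.eye(n), np.diag(W))
        base = weighted_ridge_risk(B, K, L, W, eps)
        for _ in range(10):
            V = rng.normal(size=(n, n))
            V /= np.linalg.norm(V)
            assert weighted_ridge_risk(B + 1e-3 * V, K, L, W, eps) >= base - 1e-12
            assert weighted_ridge_risk(B - 1e-3 * V, K, L, W, eps) >= base - 1e-12


class TestCounterfactualEmbedding:
    def test_scalar_reduction(self):
        # single uncensored source point, target covariate identical
        est = counterfactual_embedding(
            [2.0], [1], [[0.5]], [[0.5]],
            k_spec=KernelSpec(1.0), l_spec=KernelSpec(1.0), epsilon=0.3)
        assert est.coefficients == pytest.approx([1 / 1.3])
        assert evaluate_embedding(est, [2.0])[0] == pytest.approx(1 / 1.3)

    def test_ridge_shrinkage_limit(self, rng):
        t = rng.exponential(1.0, 20)
        X = rng.normal(size=(20, 2))
        small = counterfactual_embedding(t, np.ones(20), X, X, epsilon=0.01)
        big = counterfactual_embedding(t, np.ones(20), X, X, epsilon=1e6)
        assert np.linalg.norm(big.coefficients) < 1e-4
        assert np.linalg.norm(big.coefficients) < np.linalg.norm(small.coefficients)

    def test_censored_rows_get_zero_coefficients(self, rng):
        t = rng.exponential(1.0, 40)
        e = (rng.random(40) < 0.6).astype(int)
        X = rng.normal(size=(40, 3))
        est = counterfactual_embedding(t, e, X, rng.normal(size=(15, 3)))
        assert np.all(est.coefficients[e == 0] == 0.0)
        assert np.any(est.coefficients[e == 1] != 0.0)

    def test_covariance_operator_route_matches_closed_form(self, rng):
        # independent derivation: restricted system on uncensored atoms
        # (K_uu + n eps diag(1/W_u)) a_u = (Ktilde 1_m)_u, censored a = 0
        n = 10
        t = rng.exponential(1.0, n)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 1])
        X = rng.normal(size=(n, 2))
        Xt = rng.normal(size=(6, 2))
        k, l = KernelSpec(1.2), KernelSpec(0.9)
        eps = 0.07
        est = counterfactual_embedding(t, e, X, Xt, k_spec=k, l_spec=l, epsilon=eps)

        W = ipcw_weights(t, e, reverse_kaplan_meier(t, e))
        u = W > 0
        K = gram(X, X, k)
        b = gram(X, Xt, k).mean(axis=1)
        a_u = np.linalg.solve(K[np.ix_(u, u)] + n * eps * np.diag(1 / W[u]), b[u])
        expected = np.zeros(n)
        expected[u] = a_u
        assert np.allclose(est.coefficients, expected, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        t = rng.exponential(1.0, 30)
        e = (rng.random(30) < 0.7).astype(int)
        X = rng.normal(size=(30, 2))
        Xt = rng.normal(size=(10, 2))
        k, l = KernelSpec(1.0), KernelSpec(1.0)
        perm = rng.permutation(30)
        est = counterfactual_embedding(t, e, X, Xt, k_spec=k, l_spec=l, epsilon=0.05)
        est_p = counterfactual_embedding(t[perm], e[perm], X[perm], Xt,
                                         k_spec=k, l_spec=l, epsilon=0.05)
        grid = np.linspace(0.1, 3.0, 17)
        assert np.allclose(evaluate_embedding(est, grid),
                           evaluate_embedding(est_p, grid), atol=1e-10)

    def test_fully_censored_source_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            counterfactual_embedding([1.0, 2.0], [0, 0], [[0.0], [1.0]], [[0.5]])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            counterfactual_embedding(
                rng.exponential(1, 5), np.ones(5),
                rng.normal(size=(5, 3)), rng.normal(size=(4, 2)))


class TestEvaluation:
    def test_single_atom_unit(self):
        est = EmbeddingEstimate([2.0], [1.0], KernelSpec(1.0), 0.1)
        assert evaluate_embedding(est, [2.0])[0] == pytest.approx(1.0)

    def test_zero_coefficients_give_zero(self):
        est = EmbeddingEstimate([1.0, 2.0], [0.0, 0.0], KernelSpec(1.0), 0.1)
        assert np.all(evaluate_embedding(est, np.linspace(0, 3, 7)) == 0.0)

    def test_matches_double_loop(self, rng):
        atoms = rng.exponential(1.0, 12)
        coef = rng.normal(size=12)
        est = EmbeddingEstimate(atoms, coef, KernelSpec(0.7), 0.1)
        grid = rng.exponential(1.0, 9)
        vals = evaluate_embedding(est, grid)
        for j, g in enumerate(grid):
            expected = sum(c * np.exp(-((a - g) ** 2) / (2 * 0.7**2))
                           for a, c in zip(atoms, coef))
            assert vals[j] == pytest.approx(expected, abs=1e-12)

    def test_rkhs_distance_zero_for_identical_expansions(self, rng):
        atoms = rng.exponential(1.0, 8)
        coef = rng.normal(size=8)
        a = EmbeddingEstimate(atoms, coef, KernelSpec(1.0), 0.1)
        b = EmbeddingEstimate(atoms, coef.copy(), KernelSpec(1.0), 0.1)
        assert rkhs_distance(a, b) == pytest.approx(0.0, abs=1e-8)

    def test_rkhs_distance_matches_gram_expansion(self, rng):
        s1, s2 = rng.exponential(1.0, 5), rng.exponential(1.0, 7)
        c1, c2 = rng.normal(size=5), rng.normal(size=7)
        spec = KernelSpec(1.1)
        a = EmbeddingEstimate(s1, c1, spec, 0.1)
        b = EmbeddingEstimate(s2, c2, spec, 0.1)
        expected_sq = (c1 @ gram(s1, s1, spec) @ c1
                       - 2 * c1 @ gram(s1, s2, spec) @ c2
                       + c2 @ gram(s2, s2, spec) @ c2)
        assert rkhs_distance(a, b) == pytest.approx(np.sqrt(expected_sq), abs=1e-10)
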