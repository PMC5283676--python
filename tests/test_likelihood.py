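import numpy as np
import pytest
from scipy import stats

from conftest import make_ensemble_data
from ordbs.dag_model import ExperimentSet, assign_systematic_interventions, simulate_experiments
from ordbs.exceptions import DegenerateNodeError, ModelError, ParameterError
from ordbs.likelihood import (
    OrderingLikelihood,
    center_measurements,
    fit_means,
    fit_variances,
    fit_weights,
    log_likelihood,
    max_log_likelihood,
    total_effects,
)


def _obs(X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return ExperimentSet(X=X, interventions=tuple({} for _ in range(X.shape[0])))


class TestCentering:
    def test_single_experiment_centers_to_zero(self):
        cd = center_measurements(_obs([[3.0, 1.0]]), 0)
        assert np.all(cd.Y == 0)

    def test_two_experiments_center_to_half_difference(self):
        x1, x2 = np.array([1.0, 4.0]), np.array([3.0, 0.0])
        cd = center_measurements(_obs([x1, x2]), 1)
        assert np.allclose(cd.Y[0], (x1 - x2) / 2)

    def test_centered_mean_is_zero(self):
        _, data = make_ensemble_data(6, 1.0, 60, 20, seed=0)
        for j in range(6):
            cd = center_measurements(data, j)
            assert np.allclose(cd.Y.mean(axis=0), 0, atol=1e-12)

    def test_always_intervened_node_rejected(self):
        data = ExperimentSet(X=np.zeros((3, 2)), interventions=({0: 0.0},) * 3)
        with pytest.raises(DegenerateNodeError):
            center_measurements(data, 0)


class TestClosedFormFits:
    def test_single_node_edgeless_estimates(self):
        data = _obs([[1.0], [3.0]])
        W = fit_weights(data, [0])
        assert np.all(W == 0)
        assert fit_means(data, [0], W)[0] == pytest.approx(2.0)
        data2 = _obs([[0.0], [2.0]])
        # ML variance uses divisor N_j: ((0-1)^2 + (2-1)^2)/2 = 1
        assert fit_variances(data2, [0], np.zeros((1, 1)))[0] == pytest.approx(1.0)

    def test_noiseless_data_recovers_generating_weights(self):
        dag, data = make_ensemble_data(8, 1.0, 100, 20, seed=2, sigma_lo=0.0, sigma_hi=0.0)
        res = max_log_likelihood(data, dag.gen_order)
        assert np.abs(res.W_hat - dag.W).max() < 1e-8
        assert np.abs(res.m_hat - dag.m).max() < 1e-8
        # at or just above the variance floor on noiseless data
        assert np.all(res.sigma_hat <= 2e-8)

    def test_engine_matches_public_composition(self):
        dag, data = make_ensemble_data(7, 0.7, 70, 21, seed=3)
        order = np.random.default_rng(0).permutation(7)
        res = max_log_likelihood(data, order)
        W = fit_weights(data, order)
        m = fit_means(data, order, W)
        s = fit_variances(data, order, W)
        assert np.allclose(res.W_hat, W, atol=1e-10)
        assert np.allclose(res.m_hat, m, atol=1e-10)
        assert np.allclose(res.sigma_hat, s, atol=1e-10)
        assert res.ell_max == pytest.approx(log_likelihood(data, m, s, W), abs=1e-8)

    def test_support_respects_ordering(self):
        _, data = make_ensemble_data(6, 1.0, 60, 12, seed=4)
        order = np.array([3, 1, 5, 0, 2, 4])
        res = max_log_likelihood(data, order)
        for b in range(6):
            for a in range(b):
                assert res.W_hat[order[b], order[a]] == 0.0

    def test_per_node_blocks_equal_joint_system(self):
        # the joint normal-equation system over all p(p-1)/2 weights is
        # block-diagonal across targets; solving it whole must agree
        p = 5
        _, data = make_ensemble_data(p, 1.0, 60, 15, seed=5)
        order = np.arange(p)
        unknowns = [(a, b) for b in range(p) for a in range(b)]
        A = np.zeros((len(unknowns), len(unknowns)))
        rhs = np.zeros(len(unknowns))
        for row, (a, b) in enumerate(unknowns):
            cd = center_measurements(data, b)
            for col, (a2, b2) in enumerate(unknowns):
                if b2 == b:
                    A[row, col] = cd.Y[:, a] @ cd.Y[:, a2]
            rhs[row] = cd.Y[:, a] @ cd.Y[:, b]
        joint = np.linalg.solve(A, rhs)
        W = fit_weights(data, order)
        assert np.allclose(joint, [W[a, b] for a, b in unknowns], atol=1e-10)

    def test_label_equivariance(self):
        p = 6
        _, data = make_ensemble_data(p, 1.0, 60, 18, seed=6)
        perm = np.random.default_rng(1).permutation(p)
        X2 = data.X[:, perm]
        inv = np.argsort(perm)
        data2 = ExperimentSet(
            X=X2,
            interventions=tuple({int(inv[j]): v for j, v in J.items()} for J in data.interventions),
        )
        order = np.random.default_rng(2).permutation(p)
        res = max_log_likelihood(data, order)
        res2 = max_log_likelihood(data2, inv[order])
        assert res2.ell_max == pytest.approx(res.ell_max, abs=1e-8)
        assert np.allclose(res2.W_hat, res.W_hat[np.ix_(perm, perm)], atol=1e-8)

    def test_weight_error_decreases_with_sample_size(self):
        errors = []
        for N in (50, 200, 800):
            dag, data = make_ensemble_data(10, 1.0, N, N // 2, seed=8)
            res = max_log_likelihood(data, dag.gen_order)
            mask = dag.W != 0
            errors.append(np.abs(res.W_hat - dag.W)[mask].mean())
        assert errors[0] > errors[1] > errors[2]


class TestLogLikelihood:
    def test_single_point_at_mean_unit_sigma(self):
        data = _obs([[2.5]])
        ell = log_likelihood(data, m=[2.5], sigma=[1.0], W=np.zeros((1, 1)))
        assert ell == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_naive_per_term_density_sum(self):
        dag, data = make_ensemble_data(5, 1.0, 40, 10, seed=9)
        rng = np.random.default_rng(3)
        W = np.triu(rng.normal(size=(5, 5)), 1)
        m = rng.normal(size=5)
        sigma = rng.uniform(0.2, 1.0, 5)
        naive = 0.0
        for j in range(5):
            for k in data.K(j):
                mu = m[j] + data.X[k] @ W[:, j]
                naive += stats.norm.logpdf(data.X[k, j], mu, sigma[j])
        assert log_likelihood(data, m, sigma, W) == pytest.approx(naive, abs=1e-8)

    def test_intervened_experiment_contributes_nothing_to_its_node(self):
        _, data = make_ensemble_data(4, 1.0, 30, 0, seed=10)
        params = (np.zeros(4), np.ones(4), np.zeros((4, 4)))
        base = log_likelihood(data, *params)
        # append an experiment intervening on node 2 with an arbitrary value
        X2 = np.vstack([data.X, np.full(4, 9.0)])
        X2[-1, 2] = 7.0
        data2 = ExperimentSet(X=X2, interventions=data.interventions + ({2: 7.0},))
        with_extra = log_likelihood(data2, *params)
        # node 2 terms unchanged; only the other nodes gained a residual term
        diff = with_extra - base
        expected = sum(
            stats.norm.logpdf(X2[-1, j], 0.0, 1.0) for j in range(4) if j != 2
        )
        assert diff == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_sigma_rejected(self):
        data = _obs([[1.0, 2.0]])
        with pytest.raises(ParameterError):
            log_likelihood(data, [0, 0], [1.0, 0.0], np.zeros((2, 2)))


class TestOptimality:
    def test_mle_dominates_random_and_perturbed_parameters(self):
        dag, data = make_ensemble_data(3, 1.0, 50, 9, seed=12, sigma_lo=0.2, sigma_hi=0.5)
        res = max_log_likelihood(data, dag.gen_order)
        rng = np.random.default_rng(4)
        for _ in range(100):
            W = np.triu(rng.normal(scale=0.5, size=(3, 3)), 1)
            m = rng.normal(0.5, 1.0, 3)
            sigma = rng.uniform(0.05, 2.0, 3)
            assert log_likelihood(data, m, sigma, W) <= res.ell_max + 1e-9
        # coordinate-wise perturbations of the fit never help
        for eps in (1e-3, -1e-3):
            for j in range(3):
                m2 = res.m_hat.copy(); m2[j] += eps
                assert log_likelihood(data, m2, res.sigma_hat, res.W_hat) <= res.ell_max + 1e-12
                s2 = res.sigma_hat.copy(); s2[j] += eps
                if np.all(s2 > 0):
                    assert log_likelihood(data, res.m_hat, s2, res.W_hat) <= res.ell_max + 1e-12
            for a in range(3):
                for b in range(a + 1, 3):
                    W2 = res.W_hat.copy(); W2[a, b] += eps
                    assert log_likelihood(data, res.m_hat, res.sigma_hat, W2) <= res.ell_max + 1e-12

    def test_exchangeable_duplicate_columns_are_order_symmetric(self):
        rng = np.random.default_rng(5)
        ab = rng.normal(size=(30, 2))
        X = np.vstack([ab, ab[:, ::-1]])  # column swap == row permutation
        data = _obs(X)
        e1 = max_log_likelihood(data, [0, 1]).ell_max
        e2 = max_log_likelihood(data, [1, 0]).ell_max
        assert e1 == pytest.approx(e2, abs=1e-6)


class TestTotalEffects:
    def test_empty_graph_gives_identity(self):
        assert np.array_equal(total_effects(np.zeros((4, 4))), np.eye(4))

    def test_chain_accumulates_path_product(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 2] = 1.0
        L = total_effects(W)
        assert L[0, 2] == pytest.approx(1.0)
        assert np.allclose(L, np.eye(3) + W + W @ W)

    def test_inverse_matches_power_series(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            W = np.triu(rng.uniform(-1, 1, (10, 10)), 1)
            L = total_effects(W)
            series = sum(np.linalg.matrix_power(W, k) for k in range(10))
            assert np.abs(L - series).max() < 1e-10

    def test_cyclic_matrix_rejected(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.5
        with pytest.raises(ModelError):
            total_effects(W)
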