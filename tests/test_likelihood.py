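import numpy as np
import pytest
from scipy import optimize

import qdgame._fastfit as ff
from qdgame.data import PairedGeneProfile
from qdgame.likelihood import (AR1Params, build_ar1_covariance, fit_from_theta,
                               fit_pairwise, fit_pairwise_null, gaussian_loglik,
                               lr_interaction_test)
from qdgame.simulate import default_ar1, default_pair_spec, simulate_pairwise


class TestAR1Covariance:
    def test_uncorrelated_gives_identity(self):
        C = build_ar1_covariance(AR1Params(1.0, 1.0, 0.0, 0.0, 0.0), 2)
        np.testing.assert_allclose(C, np.eye(4))

    def test_single_block_is_ar1_toeplitz(self):
        C = build_ar1_covariance(AR1Params(1.0, 1.0, 0.5, 0.0, 0.0), 3)
        expected = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        np.testing.assert_allclose(C[:3, :3], expected)

    def test_symmetric_and_positive_definite_over_random_params(self):
        """PD is verified eigenvalue-wise whenever construction succeeds;
        matched serial correlations (Kronecker case) always succeed."""
        rng = np.random.default_rng(0)
        built = 0
        for _ in range(100):
            p = AR1Params(sigma1=rng.uniform(0.2, 2.0), sigma2=rng.uniform(0.2, 2.0),
                          rho1=rng.uniform(0.0, 0.9), rho2=rng.uniform(0.0, 0.9),
                          rho12=rng.uniform(-0.7, 0.7))
            try:
                C = build_ar1_covariance(p, 6)
            except ValueError:
                continue
            built += 1
            np.testing.assert_allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() > 0
        assert built > 50  # rejection is the exception, not the rule
        for _ in range(100):
            rho = rng.uniform(0.0, 0.95)
            p = AR1Params(sigma1=rng.uniform(0.2, 2.0), sigma2=rng.uniform(0.2, 2.0),
                          rho1=rho, rho2=rho, rho12=rng.uniform(-0.95, 0.95))
            C = build_ar1_covariance(p, 6)
            assert np.linalg.eigvalsh(C).min() > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AR1Params(1.0, 1.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            AR1Params(-1.0, 1.0, 0.0, 0.0, 0.0)


class TestGaussianLoglik:
    def test_standard_normal_at_zero(self):
        for d in (1, 4, 7):
            ll = gaussian_loglik(np.zeros(d), np.eye(d))
            assert ll == pytest.approx(-(d / 2) * np.log(2 * np.pi))

    def test_matches_bruteforce_density_on_6x6(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            A = rng.normal(size=(6, 6))
            C = A @ A.T + 6 * np.eye(6)
            r = rng.normal(size=6)
            brute = (-0.5 * (6 * np.log(2 * np.pi) + np.log(np.linalg.det(C))
                             + r @ np.linalg.inv(C) @ r))
            assert gaussian_loglik(r, C) == pytest.approx(brute, abs=1e-10)

    def test_covariance_scaling_shifts_by_half_d_log_c(self):
        d, c = 5, 3.7
        base = gaussian_loglik(np.zeros(d), np.eye(d))
        scaled = gaussian_loglik(np.zeros(d), c * np.eye(d))
        assert scaled - base == pytest.approx(-(d / 2) * np.log(c))

    def test_kernel_matches_public_implementation(self):
        """The compiled negative-loglik equals the dense-algebra route."""
        rng = np.random.default_rng(5)
        n = 8
        resid = rng.normal(size=2 * n)
        p = AR1Params(1.3, 0.7, 0.4, 0.2, 0.3)
        C = build_ar1_covariance(p, n)
        assert ff._mvn_nll(resid, C) == pytest.approx(-gaussian_loglik(resid, C),
                                                      abs=1e-9)


@pytest.fixture(scope="module")
def game_profile():
    spec = default_pair_spec(3.0, 3.0)
    prof, truth = simulate_pairwise(spec, default_ar1(), n=30, seed=11)
    return prof, truth


@pytest.fixture(scope="module")
def null_profile():
    spec = default_pair_spec(0.0, 0.0)
    prof, truth = simulate_pairwise(spec, default_ar1(), n=30, seed=12)
    return prof, truth


class TestPairwiseFits:
    def test_parameter_count_difference_is_two_lop_orders(self, null_profile):
        prof, _ = null_profile
        null = fit_pairwise_null(prof, seed=0, n_starts=2)
        full = fit_pairwise(prof, seed=0, n_starts=2, null_fit=null)
        assert full.n_params - null.n_params == 2 * 3

    def test_nested_model_dominance(self, game_profile, null_profile):
        for prof, _ in (game_profile, null_profile):
            null = fit_pairwise_null(prof, seed=0, n_starts=2)
            full = fit_pairwise(prof, seed=0, n_starts=2, null_fit=null)
            assert full.loglik >= null.loglik - 1e-6

    def test_null_fit_recovers_power_parameters(self):
        spec = default_pair_spec(0.0, 0.0)
        prof, truth = simulate_pairwise(spec, default_ar1(0.5), n=50, seed=21)
        null = fit_pairwise_null(prof, seed=0, n_starts=3)
        a1, b1 = null.spec.independent["type1"]
        a2, b2 = null.spec.independent["type2"]
        assert a1 == pytest.approx(0.25, rel=0.10)
        assert b1 == pytest.approx(1.4, rel=0.10)
        assert a2 == pytest.approx(0.8, rel=0.10)
        assert b2 == pytest.approx(0.7, rel=0.10)

    def test_fit_loglik_at_least_generating_parameters(self, game_profile):
        """The optimizer should beat the truth's own likelihood on noisy data."""
        prof, truth = game_profile
        null = fit_pairwise_null(prof, seed=0, n_starts=2)
        full = fit_pairwise(prof, seed=0, n_starts=3, null_fit=null)
        # evaluate the likelihood at the generating parameter values
        grid, y1, y2 = prof.sorted_arrays()
        v1, v2 = truth.spec.node_ids
        a1, b1 = truth.spec.independent[v1]
        a2, b2 = truth.spec.independent[v2]
        ar1 = truth.ar1
        th = np.concatenate([
            [np.log(a1), b1, np.log(a2), b2],
            truth.spec.edges[(v1, v2)], truth.spec.edges[(v2, v1)],
            [np.log(ar1.sigma1), np.log(ar1.sigma2),
             np.arctanh(ar1.rho1 / ff.RHO_MAX), np.arctanh(ar1.rho2 / ff.RHO_MAX),
             np.arctanh(ar1.rho12 / ff.RHO12_MAX)],
        ])
        at_truth = fit_from_theta(prof, th, mode=1)
        assert full.loglik >= at_truth.loglik - 1e-6

    def test_mean_decomposition_conserves(self, game_profile):
        prof, _ = game_profile
        null = fit_pairwise_null(prof, seed=0, n_starts=2)
        full = fit_pairwise(prof, seed=0, n_starts=2, null_fit=null)
        dec = full.decomposition
        for v in full.spec.node_ids:
            total = dec.indep[v] + sum(c for (t, _), c in dec.dep.items() if t == v)
            np.testing.assert_allclose(dec.mean[v], total, atol=1e-8)

    def test_too_few_units_rejected(self):
        prof = PairedGeneProfile("g", [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            fit_pairwise_null(prof)


class TestKernelOptimizer:
    def test_nelder_mead_matches_scipy_on_shared_objective(self):
        """The compiled simplex search lands where scipy's does."""
        spec = default_pair_spec(0.0, 0.0)
        prof, _ = simulate_pairwise(spec, default_ar1(), n=12, seed=33)
        grid, y1, y2 = prof.sorted_arrays()
        from qdgame.likelihood import _edge_domain, _moment_theta9

        dom1, dom2 = _edge_domain(y1), _edge_domain(y2)
        x0 = _moment_theta9(grid, y1, y2)
        zeros = np.zeros(0)

        def obj(x):
            return ff._neg_loglik(x, 0, 0, zeros, grid, y1, y2, dom1, dom2, 40)

        ours, f_ours, _ = ff._nelder_mead(
            x0, np.maximum(0.1 * np.abs(x0), 0.05), 0, 0, zeros,
            grid, y1, y2, dom1, dom2, 40, 2000, 1e-10)
        ref = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "fatol": 1e-10,
                                         "xatol": 1e-8})
        assert f_ours == pytest.approx(ref.fun, abs=0.5)


class TestInteractionTest:
    def test_lr_nonnegative_and_fields(self, game_profile):
        prof, _ = game_profile
        res = lr_interaction_test(prof, n_perm=19, seed=0, protocol="fast",
                                  return_samples=True)
        assert res["LR"] >= -1e-6
        assert res["threshold"] >= 0
        assert res["n_perm_effective"] <= 19
        assert len(res["samples"]) == res["n_perm_effective"]

    def test_strong_coupling_detected(self):
        spec = default_pair_spec(3.0, 3.0)
        prof, _ = simulate_pairwise(spec, default_ar1(), n=50, seed=2)
        res = lr_interaction_test(prof, n_perm=39, seed=0, protocol="fast")
        assert res["significant"]

    def test_n_perm_minimum_enforced(self, game_profile):
        with pytest.raises(ValueError):
            lr_interaction_test(game_profile[0], n_perm=10, seed=0)
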