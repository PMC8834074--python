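import numpy as np
import pytest
from scipy.special import eval_legendre

from qdgame.ode import (LOPBasis, QdodeSpec, decompose, dependent_rate,
                        independent_rate, lop_evaluate, solve_qdode)


class TestLegendre:
    @pytest.mark.parametrize("order, x, expected", [
        (0, 0.7, 1.0),
        (1, 0.3, 0.3),
        (2, 0.5, -0.125),
    ])
    def test_low_orders_closed_form(self, order, x, expected):
        assert lop_evaluate(order, x) == pytest.approx(expected)

    def test_matches_scipy_reference(self):
        x = np.linspace(-1, 1, 21)
        for r in range(6):
            np.testing.assert_allclose(lop_evaluate(r, x), eval_legendre(r, x),
                                       atol=1e-12)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            lop_evaluate(2, 1.5)


class TestRates:
    def test_independent_rate_is_power_derivative(self):
        assert independent_rate(2.0, 0.5, 4.0) == pytest.approx(0.5)
        # beta = 1 gives a constant rate alpha
        for N in (0.5, 3.0, 10.0):
            assert independent_rate(1.7, 1.0, N) == pytest.approx(1.7)

    def test_independent_rate_matches_finite_difference(self):
        alpha, beta = 1.3, 0.8
        for N in (0.5, 2.0, 7.0):
            h = 1e-6 * N
            fd = (alpha * (N + h) ** beta - alpha * (N - h) ** beta) / (2 * h)
            assert independent_rate(alpha, beta, N) == pytest.approx(fd, rel=1e-6)

    def test_dependent_rate_zero_coeffs_and_midpoint(self):
        basis = LOPBasis(3, (0.0, 2.0))
        assert dependent_rate(np.zeros(3), 1.3, basis) == 0.0
        # a single P1 coefficient vanishes at the domain midpoint
        assert dependent_rate(np.array([2.5]), 1.0, LOPBasis(1, (0.0, 2.0))) == pytest.approx(0.0)

    def test_dependent_rate_matches_direct_summation(self):
        basis = LOPBasis(4, (-1.0, 3.0))
        coeffs = np.array([0.3, -0.7, 0.2, 0.05])
        for x in (-0.5, 0.0, 1.2, 2.9):
            z = 2 * (x - (-1.0)) / 4.0 - 1.0
            direct = sum(c * eval_legendre(r + 1, z) for r, c in enumerate(coeffs))
            assert dependent_rate(coeffs, x, basis) == pytest.approx(direct, abs=1e-12)

    def test_clamps_out_of_domain_source(self):
        basis = LOPBasis(2, (0.0, 1.0))
        assert dependent_rate(np.array([1.0, 0.0]), 5.0, basis) == pytest.approx(1.0)


def _decoupled_spec(alpha=2.0, beta=0.5, lo=1.0):
    return QdodeSpec(
        node_ids=["a", "b"],
        independent={"a": (alpha, beta), "b": (1.0, 1.0)},
        edges={},
        lop=LOPBasis(3, (0.0, 10.0)),
        initial={"a": alpha * lo ** beta, "b": lo},
    )


class TestSolver:
    def test_no_edges_recovers_power_curve(self):
        grid = np.linspace(1.0, 9.0, 50)
        traj = solve_qdode(_decoupled_spec(), grid)
        np.testing.assert_allclose(traj["a"], 2.0 * grid ** 0.5, atol=1e-6)
        np.testing.assert_allclose(traj["b"], grid, atol=1e-10)

    def test_zero_rate_stays_at_initial(self):
        spec = QdodeSpec(node_ids=["a"], independent={"a": (0.0, 0.5)},
                         edges={}, lop=LOPBasis(2, (0.0, 1.0)),
                         initial={"a": 3.0})
        traj = solve_qdode(spec, np.linspace(1, 5, 10))
        np.testing.assert_allclose(traj["a"], 3.0)

    def test_rk4_fourth_order_convergence(self):
        grid = np.linspace(1.0, 9.0, 8)
        exact = 2.0 * grid ** 0.5
        # nonlinear-in-N rate integrated with few vs many substeps
        err = []
        for substeps in (4, 8):
            traj = solve_qdode(_decoupled_spec(), grid, substeps=substeps)
            err.append(np.max(np.abs(traj["a"] - exact)))
        assert err[1] < err[0] / 8.0

    def test_symmetric_pair_stays_symmetric(self):
        basis = LOPBasis(2, (0.0, 10.0))
        spec = QdodeSpec(
            node_ids=["a", "b"],
            independent={"a": (1.0, 0.8), "b": (1.0, 0.8)},
            edges={("a", "b"): np.array([0.4, -0.1]),
                   ("b", "a"): np.array([0.4, -0.1])},
            lop=basis,
            initial={"a": 1.0, "b": 1.0},
        )
        traj = solve_qdode(spec, np.linspace(1, 6, 20))
        np.testing.assert_allclose(traj["a"], traj["b"], atol=1e-12)

    def test_grid_refinement_invariance(self):
        spec = _decoupled_spec(alpha=1.2, beta=1.3)
        spec.initial["a"] = 1.2
        coarse = np.linspace(1.0, 5.0, 5)
        fine = np.linspace(1.0, 5.0, 9)  # shares the coarse points
        t1 = solve_qdode(spec, coarse)
        t2 = solve_qdode(spec, fine)
        np.testing.assert_allclose(t1["a"], t2["a"][::2], atol=1e-6)

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            solve_qdode(_decoupled_spec(), np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            solve_qdode(_decoupled_spec(), np.array([-1.0, 2.0]))


class TestDecompose:
    def _coupled_spec(self):
        return QdodeSpec(
            node_ids=["a", "b"],
            independent={"a": (0.5, 1.2), "b": (1.5, 0.6)},
            edges={("a", "b"): np.array([0.5, -0.3, 0.2]),
                   ("b", "a"): np.array([-0.2, 0.4, 0.1])},
            lop={("a", "b"): LOPBasis(3, (0.5, 6.0)),
                 ("b", "a"): LOPBasis(3, (0.2, 8.0))},
            initial={"a": 0.5, "b": 1.5},
        )

    def test_no_edges_means_equal_indep(self):
        grid = np.linspace(1, 9, 15)
        dec = decompose(_decoupled_spec(), grid)
        assert dec.dep == {}
        np.testing.assert_allclose(dec.mean["a"], dec.indep["a"])

    def test_conservation_mean_is_sum_of_components(self):
        grid = np.linspace(1.0, 7.0, 25)
        spec = self._coupled_spec()
        dec = decompose(spec, grid)
        for v in spec.node_ids:
            total = dec.indep[v].copy()
            for (t, s), curve in dec.dep.items():
                if t == v:
                    total = total + curve
            np.testing.assert_allclose(dec.mean[v], total, atol=1e-8)

    def test_decomposition_consistent_with_solver(self):
        grid = np.linspace(1.0, 7.0, 25)
        spec = self._coupled_spec()
        traj = solve_qdode(spec, grid)
        dec = decompose(spec, grid)
        for v in spec.node_ids:
            np.testing.assert_allclose(dec.mean[v], traj[v], atol=1e-8)

    def test_dep_curves_start_at_zero_and_net_dep(self):
        grid = np.linspace(1.0, 7.0, 25)
        dec = decompose(self._coupled_spec(), grid)
        for e, curve in dec.dep.items():
            assert curve[0] == 0.0
            assert dec.net_dep[e] == pytest.approx(curve[-1])


class TestSpecSerialization:
    def test_json_round_trip(self):
        spec = QdodeSpec(
            node_ids=["a", "b"],
            independent={"a": (0.5, 1.2), "b": (1.5, 0.6)},
            edges={("a", "b"): np.array([0.5, -0.3, 0.2])},
            lop={("a", "b"): LOPBasis(3, (0.5, 6.0))},
            initial={"a": 0.5, "b": 1.5},
        )
        back = QdodeSpec.from_json(spec.to_json())
        assert back.node_ids == spec.node_ids
        np.testing.assert_allclose(back.edges[("a", "b")], spec.edges[("a", "b")])
        assert back.edge_basis("a", "b").domain == (0.5, 6.0)

    def test_rejects_self_edges_and_bad_lengths(self):
        with pytest.raises(ValueError):
            QdodeSpec(node_ids=["a"], independent={"a": (1, 1)},
                      edges={("a", "a"): np.array([1.0])},
                      lop=LOPBasis(1, (0, 1)), initial={"a": 1.0})
        with pytest.raises(ValueError):
            QdodeSpec(node_ids=["a", "b"], independent={"a": (1, 1), "b": (1, 1)},
                      edges={("a", "b"): np.array([1.0, 2.0])},
                      lop=LOPBasis(3, (0, 1)), initial={"a": 1.0, "b": 1.0})
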