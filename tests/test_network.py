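import numpy as np
import pandas as pd
import pytest

from qdgame.data import ExpressionTable, IndexedSeries
from qdgame.network import (SparseNetwork, classify_network_roles, fit_network,
                            hubness, lasso_select, module_network)


class TestLassoSelect:
    def test_planted_single_predictor_found(self):
        rng = np.random.default_rng(0)
        grid = np.linspace(1, 10, 60)
        cands = {i: IndexedSeries(grid, rng.normal(0, 1, 60)) for i in range(10)}
        focal = IndexedSeries(grid, 2.0 * cands[3].values + rng.normal(0, 0.1, 60))
        sel = lasso_select(focal, cands, max_predictors=3, seed=0)
        assert sel[0] == 3

    def test_pure_noise_usually_selects_nothing(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(1, 10, 50)
        hits = 0
        for rep in range(10):
            cands = {i: IndexedSeries(grid, rng.normal(0, 1, 50)) for i in range(8)}
            focal = IndexedSeries(grid, rng.normal(0, 1, 50))
            hits += len(lasso_select(focal, cands, max_predictors=3, seed=rep)) > 0
        assert hits <= 4

    def test_max_predictors_cap(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(1, 10, 60)
        cands = {i: IndexedSeries(grid, rng.normal(0, 1, 60)) for i in range(6)}
        focal = IndexedSeries(grid, sum(c.values for c in cands.values()))
        sel = lasso_select(focal, cands, max_predictors=1, seed=0)
        assert len(sel) <= 1

    def test_degenerate_focal_rejected(self):
        grid = np.linspace(1, 10, 20)
        cands = {0: IndexedSeries(grid, np.sin(grid))}
        with pytest.raises(ValueError):
            lasso_select(IndexedSeries(grid, np.ones(20)), cands, 1)


def _toy_network():
    """Hand-built 3-node network with polynomial dependent curves."""
    grid = np.linspace(0.0, 2.0, 201)
    indep = {
        "a": 1.0 + grid,            # integral area 4
        "b": 2.0 + 0.0 * grid,      # area 4
        "c": grid ** 2,             # area 8/3
    }
    edges = {
        ("b", "a"): {"curve": grid * (2 - grid), "sign": 1,
                     "weight": 4 / 3, "net_dep": 0.0, "sign_change": False},
        ("c", "a"): {"curve": -0.5 * grid, "sign": -1,
                     "weight": 1.0, "net_dep": -1.0, "sign_change": False},
    }
    net = SparseNetwork(
        node_ids=["a", "b", "c"], grid=grid,
        node_indep={v: {"alpha": 1, "beta": 1, "curve": c}
                    for v, c in indep.items()},
        edges=edges,
    )
    return net


class TestHubness:
    def test_no_out_edges_gives_zero(self):
        net = _toy_network()
        assert hubness(net, "b") == 0.0
        assert hubness(net, "c") == 0.0

    def test_single_edge_ratio(self):
        grid = np.linspace(0.0, 2.0, 201)
        net = SparseNetwork(
            node_ids=["a", "b"], grid=grid,
            node_indep={"a": {"alpha": 1, "beta": 1, "curve": 0 * grid},
                        "b": {"alpha": 1, "beta": 1, "curve": 2 + 0 * grid}},
            edges={("b", "a"): {"curve": 1 + 0 * grid, "sign": 1, "weight": 2,
                                "net_dep": 1.0, "sign_change": False}},
        )
        # |dep| integral 2.0 over target indep integral 4.0
        assert hubness(net, "a") == pytest.approx(0.5, rel=1e-10)

    def test_matches_fine_grid_quadrature(self):
        net = _toy_network()
        h = hubness(net, "a")
        # closed forms: |x(2-x)| over [0,2] integrates to 4/3; b's indep to 4
        # |-x/2| integrates to 1; c's indep x^2 to 8/3
        exact = (4 / 3) / 4 + 1.0 / (8 / 3)
        assert h == pytest.approx(exact, rel=1e-4)

    def test_additive_over_outgoing_edges(self):
        net = _toy_network()
        h_total = hubness(net, "a")
        single = {}
        for e in list(net.edges):
            removed = dict(net.edges)
            kept = {e: removed.pop(e)}
            sub = SparseNetwork(net.node_ids, net.grid, net.node_indep, kept)
            single[e] = hubness(sub, "a")
        assert h_total == pytest.approx(sum(single.values()), rel=1e-12)


class TestRoles:
    def test_role_rules(self):
        net = _toy_network()
        roles = classify_network_roles(net)
        assert roles == {"a": "primary_hub", "b": "subordinate", "c": "subordinate"}

    def test_isolated_node_is_subordinate(self):
        net = SparseNetwork(["x"], np.linspace(1, 2, 5),
                            {"x": {"alpha": 1, "beta": 0, "curve": np.ones(5)}}, {})
        assert classify_network_roles(net)["x"] == "subordinate"

    def test_secondary_hub_has_in_and_out(self):
        grid = np.linspace(0, 1, 11)
        curve = {"curve": grid, "sign": 1, "weight": 0.5, "net_dep": 1.0,
                 "sign_change": False}
        net = SparseNetwork(
            ["a", "b", "c"], grid,
            {v: {"alpha": 1, "beta": 1, "curve": 1 + grid} for v in "abc"},
            {("b", "a"): dict(curve), ("c", "b"): dict(curve)},
        )
        assert classify_network_roles(net)["b"] == "secondary_hub"


class TestFitNetwork:
    def test_single_node_network_has_no_edges(self):
        grid = np.sort(np.random.default_rng(0).uniform(1, 10, 30))
        y = 2.0 * grid ** 0.8
        table = ExpressionTable(pd.DataFrame([y], index=["g1"],
                                             columns=[f"s{i}" for i in range(30)]))
        net = fit_network(table, grid, seed=0)
        assert net.edges == {}
        assert net.node_indep["g1"]["alpha"] == pytest.approx(2.0, rel=0.05)

    def test_decomposition_conservation(self):
        from qdgame.simulate import simulate_network

        table, grid, _ = simulate_network(m=5, regulators_per_node=1,
                                          coupling_scale=1.0, n=40, seed=9)
        net = fit_network(table, grid, seed=0)
        for v in net.node_ids:
            total = net.node_indep[v]["curve"].copy()
            for (t, s), e in net.edges.items():
                if t == v:
                    total = total + e["curve"]
            np.testing.assert_allclose(net.node_mean[v], total, atol=1e-8)

    def test_edge_cap_respected(self):
        from qdgame.simulate import simulate_network

        table, grid, _ = simulate_network(m=6, regulators_per_node=2,
                                          coupling_scale=1.0, n=40, seed=10)
        net = fit_network(table, grid, max_predictors=2, seed=0)
        for v in net.node_ids:
            assert len(net.in_edges(v)) <= 2

    def test_edge_weight_is_absolute_net_area(self):
        from qdgame.simulate import simulate_network

        table, grid, _ = simulate_network(m=5, regulators_per_node=1,
                                          coupling_scale=1.2, n=40, seed=11)
        net = fit_network(table, grid, seed=0)
        for (t, s), e in net.edges.items():
            area = np.trapezoid(e["curve"], net.grid)
            assert e["weight"] == pytest.approx(abs(area))
            if area != 0:
                assert e["sign"] == int(np.sign(area))


class TestModuleNetwork:
    def test_two_modules_two_stages_shapes(self, small_table):
        from qdgame.allometry import ModuleAssignment

        assignment = ModuleAssignment(K=2, labels=np.array([1, 1, 2, 2]),
                                      module_fits={}, aic=0.0, loglik=0.0,
                                      n_params=0, converged=True)
        nets = module_network(small_table, assignment, min_samples=2)
        # strata with enough samples only; each network has 2 module nodes
        for key, net in nets.items():
            assert len(net.node_ids) == 2

    def test_gene_permutation_leaves_module_means_invariant(self, small_table):
        from qdgame.allometry import ModuleAssignment

        labels = np.array([1, 2, 1, 2])
        a1 = ModuleAssignment(K=2, labels=labels, module_fits={}, aic=0, loglik=0,
                              n_params=0, converged=True)
        perm = [2, 3, 0, 1]
        permuted = ExpressionTable(small_table.values.iloc[perm],
                                   small_table.col_meta)
        a2 = ModuleAssignment(K=2, labels=labels[perm], module_fits={}, aic=0,
                              loglik=0, n_params=0, converged=True)
        n1 = module_network(small_table, a1, min_samples=2)
        n2 = module_network(permuted, a2, min_samples=2)
        for key in n1:
            np.testing.assert_allclose(n1[key].grid, n2[key].grid)
            for v in n1[key].node_ids:
                np.testing.assert_allclose(n1[key].node_indep[v]["curve"],
                                           n2[key].node_indep[v]["curve"])
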