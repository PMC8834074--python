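"""Sparse signed directed qdODE networks from high-dimensional expression.

Each variable (gene, module or cell) is a node whose EI-indexed series is
decomposed into an independent power-curve integral plus dependent Legendre
integrals contributed by a LASSO-selected set of regulators.  Fitting is
*decoupled*: each node is fit conditioning on power-curve smoothers of its
selected sources' observations, which makes the dependent component linear
in the Legendre coefficients so they (and the residual scale) profile out of
the AR(1) Gaussian likelihood in closed form; only the focal node's power
parameters and serial correlation are optimized numerically.  Edges carry a
sign (net activation/inhibition), a weight (absolute net area of the
dependent curve) and the curve itself; node-level outgoing hubness sums the
ratio of each outgoing dependent curve's absolute area to the target's
independent-curve area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.integrate import cumulative_trapezoid

from .allometry import fit_power_law
from .data import ExpressionTable, IndexedSeries
from .ode import LOPBasis

logger = logging.getLogger(__name__)

DEFAULT_MAX_PREDICTORS = 3
DEFAULT_LOP_ORDER = 3


@dataclass
class SparseNetwork:
    """Signed, weighted, directed interaction network with curve attributes.

    ``node_indep[v]`` holds (alpha, beta) and the independent curve on
    ``grid``; ``edges[(target, source)]`` holds sign, weight and the
    dependent curve; ``hubness[v]`` the outgoing-hubness coefficient.
    """

    node_ids: list
    grid: np.ndarray
    node_indep: dict
    edges: dict
    hubness: dict = field(default_factory=dict)
    node_mean: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def out_edges(self, node) -> list:
        return [e for e in self.edges if e[1] == node]

    def in_edges(self, node) -> list:
        return [e for e in self.edges if e[0] == node]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        roles = classify_network_roles(self)
        for v in self.node_ids:
            g.add_node(v, alpha=self.node_indep[v]["alpha"],
                       beta=self.node_indep[v]["beta"],
                       hubness=self.hubness.get(v, 0.0), role=roles[v])
        for (t, s), e in self.edges.items():
            g.add_edge(s, t, sign=e["sign"], weight=e["weight"])
        return g


def lasso_select(focal: IndexedSeries, candidates: dict, max_predictors: int,
                 seed: int = 0) -> list:
    """LASSO + adaptive-LASSO selection of the regulators of a focal series.

    ``candidates`` maps candidate id -> IndexedSeries on the focal's grid (or
    id -> list of series for grouped two-view candidates, selected by the
    group l2 norm of their coefficients).  The cross-validated first pass
    sets adaptive weights 1/|coef|; survivors of the adaptive pass are
    ranked by |coef| and truncated to ``max_predictors``.
    """
    from sklearn.linear_model import LassoCV

    if not candidates:
        raise ValueError("no candidates")
    y = np.asarray(focal.values, dtype=float)
    if np.std(y) < 1e-12:
        raise ValueError("degenerate (constant) focal series")

    ids = list(candidates)
    cols, col_group = [], []
    for gi, cid in enumerate(ids):
        entry = candidates[cid]
        series_list = entry if isinstance(entry, (list, tuple)) else [entry]
        for s in series_list:
            if len(s) != len(focal):
                raise ValueError("candidate series must share the focal grid")
            cols.append(np.asarray(s.values, dtype=float))
            col_group.append(gi)
    X = np.column_stack(cols)
    col_group = np.asarray(col_group)

    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    yc = y - y.mean()

    n = len(y)
    cv = min(5, max(3, n // 5))
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    las = LassoCV(cv=cv, random_state=seed, alphas=60, max_iter=50000, tol=1e-3)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        las.fit(Xs, yc)
    coef = las.coef_
    nz = np.abs(coef) > 1e-10
    if not nz.any():
        return []

    # adaptive pass: rescale surviving columns by |coef| (weights 1/|coef|)
    Xa = Xs[:, nz] * np.abs(coef[nz])
    las2 = LassoCV(cv=cv, random_state=seed, alphas=60, max_iter=50000, tol=1e-3)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        las2.fit(Xa, yc)
    final = np.zeros_like(coef)
    final[nz] = las2.coef_ * np.abs(coef[nz])

    group_norm = np.zeros(len(ids))
    for gi in range(len(ids)):
        group_norm[gi] = np.linalg.norm(final[col_group == gi])
    selected = [gi for gi in np.argsort(-group_norm) if group_norm[gi] > 1e-10]
    return [ids[gi] for gi in selected[:max_predictors]]


def _bic_prune(grid: np.ndarray, resid: np.ndarray, selected: list,
               basis_cols: dict) -> list:
    """Keep the BIC-best subset of the LASSO-selected regulators.

    Cross-validated LASSO controls prediction error, not false discovery;
    on pure-noise networks it admits spurious smooth regressors.  An
    exhaustive BIC comparison over the (small) selected set prunes them.
    """
    import itertools

    if not selected:
        return []
    n = grid.size
    best = (np.inf, [])
    for size in range(len(selected) + 1):
        for sub in itertools.combinations(selected, size):
            X = np.column_stack(
                [np.ones((n, 1))] + [np.column_stack([s.values for s in basis_cols[u]])
                                     for u in sub])
            coef, *_ = np.linalg.lstsq(X, resid, rcond=None)
            rss = float(np.sum((resid - X @ coef) ** 2))
            bic = n * np.log(max(rss, 1e-300) / n) + np.log(n) * X.shape[1]
            if bic < best[0]:
                best = (bic, list(sub))
    return best[1]


def _ar1_corr_inverse_factors(n: int, rho: float):
    """log|R| and the tridiagonal inverse of the AR(1) correlation matrix."""
    logdet = (n - 1) * np.log(1 - rho ** 2)
    main = np.full(n, 1.0 + rho ** 2)
    main[0] = main[-1] = 1.0
    off = np.full(n - 1, -rho)
    return logdet, main / (1 - rho ** 2), off / (1 - rho ** 2)


def _quad_form(main, off, a, b):
    """a' R^{-1} b for tridiagonal R^{-1} given by (main, off)."""
    s = np.sum(main * a * b)
    s += np.sum(off * (a[:-1] * b[1:] + a[1:] * b[:-1]))
    return s


def _basis_integrals(grid: np.ndarray, smoother, basis: LOPBasis,
                     refine: int = 8) -> np.ndarray:
    """Cumulative integrals of each Legendre basis term along the grid.

    ``smoother(N)`` gives the source node's pinned trajectory; the integrand
    P_r(map(smoother(N))) is sampled on a refined grid and integrated by the
    trapezoid rule, then read off at the observation points.
    """
    fine = [grid[0]]
    for a, b in zip(grid[:-1], grid[1:]):
        fine.extend(np.linspace(a, b, refine + 1)[1:])
    fine = np.asarray(fine)
    design = basis.design(smoother(fine))  # (len(fine), order)
    cum = cumulative_trapezoid(design, fine, axis=0, initial=0.0)
    take = np.searchsorted(fine, grid)
    return cum[take]


def _fit_node(grid: np.ndarray, y: np.ndarray, sources: list,
              smoothers: dict, lop_order: int):
    """Decoupled single-node fit; returns fitted parameters and curves.

    The mean is  y0 + alpha*(N^beta - N0^beta) + B @ c  with B the stacked
    per-source Legendre cumulative integrals; c and the residual scale are
    profiled out of the AR(1) likelihood, so the numeric search runs over
    (log alpha, beta, atanh rho) only.
    """
    n = grid.size
    y0 = y[0]
    bases = {}
    blocks = []
    for u in sources:
        vals_u = smoothers[u]["obs"]
        lo, hi = float(np.min(vals_u)), float(np.max(vals_u))
        if hi - lo < 1e-9:
            pad = max(0.5, 0.1 * abs(hi))
            lo, hi = lo - pad, hi + pad
        basis = LOPBasis(lop_order, (lo, hi))
        bases[u] = basis
        blocks.append(_basis_integrals(grid, smoothers[u]["fn"], basis))
    B = np.column_stack(blocks) if blocks else np.empty((n, 0))
    p = B.shape[1]

    pf = fit_power_law(IndexedSeries(grid, y))
    x0 = np.array([np.log(max(pf.alpha, 1e-8)), pf.beta, 0.0])

    def concentrated(params):
        la, beta, zr = params
        la = np.clip(la, -25, 25)
        beta = np.clip(beta, -12, 12)
        rho = np.tanh(np.clip(zr, -5, 5))
        indep = y0 + np.exp(la) * (grid ** beta - grid[0] ** beta)
        resid0 = y - indep
        logdetR, main, off = _ar1_corr_inverse_factors(n, rho)
        if p:
            G = np.empty((p, p))
            h = np.empty(p)
            for a in range(p):
                h[a] = _quad_form(main, off, B[:, a], resid0)
                for b in range(a, p):
                    G[a, b] = G[b, a] = _quad_form(main, off, B[:, a], B[:, b])
            try:
                c = np.linalg.solve(G + 1e-10 * np.eye(p), h)
            except np.linalg.LinAlgError:
                return 1e12, None, None
            resid = resid0 - B @ c
        else:
            c = np.empty(0)
            resid = resid0
        q = _quad_form(main, off, resid, resid)
        if q <= 0 or not np.isfinite(q):
            return 1e12, None, None
        sigma2 = q / n
        nll = 0.5 * (n * np.log(2 * np.pi * sigma2) + logdetR + n)
        return nll, c, sigma2

    sol = optimize.minimize(lambda x: concentrated(x)[0], x0,
                            method="Nelder-Mead",
                            options={"maxiter": 600, "fatol": 1e-9, "xatol": 1e-7})
    nll, c, sigma2 = concentrated(sol.x)
    la, beta, zr = sol.x
    alpha = float(np.exp(np.clip(la, -25, 25)))
    beta = float(np.clip(beta, -12, 12))
    rho = float(np.tanh(np.clip(zr, -5, 5)))
    indep_curve = y0 + alpha * (grid ** beta - grid[0] ** beta)
    dep_curves = {}
    for k, u in enumerate(sources):
        dep_curves[u] = B[:, k * lop_order:(k + 1) * lop_order] @ c[k * lop_order:(k + 1) * lop_order]
    return {
        "alpha": alpha, "beta": beta, "rho": rho,
        "sigma2": float(sigma2) if sigma2 is not None else np.nan,
        "loglik": float(-nll), "indep_curve": indep_curve,
        "dep_curves": dep_curves, "coeffs": c, "bases": bases,
    }


def _edge_summary(grid: np.ndarray, curve: np.ndarray) -> dict:
    area = float(np.trapezoid(curve, grid))
    sign = int(np.sign(area)) if area != 0 else 0
    crosses = bool(np.min(curve) < -1e-9 and np.max(curve) > 1e-9)
    return {"sign": sign, "weight": abs(area), "curve": curve,
            "net_dep": float(curve[-1]), "sign_change": crosses}


def fit_network(table: ExpressionTable, index: np.ndarray,
                max_predictors: int = DEFAULT_MAX_PREDICTORS,
                lop_order: int = DEFAULT_LOP_ORDER, seed: int = 0) -> SparseNetwork:
    """Infer a sparse signed directed network among the table's rows.

    Columns are serialized by ascending ``index`` (the EI grid).  Per focal
    node: LASSO-select at most ``max_predictors`` regulators, then fit the
    node's decoupled qdODE by maximum likelihood with AR(1) errors.
    """
    index = np.asarray(index, dtype=float)
    vals = table.values.to_numpy(dtype=float)
    order = np.argsort(index, kind="stable")
    from .data import _break_ties
    grid = _break_ties(index[order])
    Y = vals[:, order]
    nodes = [str(r) for r in table.values.index]

    series = {v: IndexedSeries(grid, Y[i]) for i, v in enumerate(nodes)}
    # sources are pinned to their observed series (linear interpolation):
    # a source's distinguishing features — turning points, bends — live in
    # its observations, and replacing them with a fitted power curve would
    # collapse all same-direction sources onto one smooth shape and make
    # regulator identities indistinguishable
    smoothers = {}
    for i, v in enumerate(nodes):
        obs = Y[i]
        fn = (lambda o: (lambda N: np.interp(N, grid, o)))(obs)
        smoothers[v] = {"fn": fn, "obs": obs}

    # per-source Legendre basis-integral columns: the model's dependent
    # curves are linear in these, so selection runs on them (grouped per
    # source) against each focal node's de-trended series; regressing raw
    # values on raw values would be dominated by the allometric trend all
    # nodes share
    basis_cols = {}
    for v in nodes:
        obs = smoothers[v]["obs"]
        lo, hi = float(np.min(obs)), float(np.max(obs))
        if hi - lo < 1e-9:
            pad = max(0.5, 0.1 * abs(hi))
            lo, hi = lo - pad, hi + pad
        B = _basis_integrals(grid, smoothers[v]["fn"], LOPBasis(lop_order, (lo, hi)))
        basis_cols[v] = [IndexedSeries(grid, B[:, q]) for q in range(lop_order)]

    node_indep, edges, node_mean = {}, {}, {}
    for i, v in enumerate(nodes):
        try:
            cands = {u: basis_cols[u] for u in nodes if u != v}
            if cands:
                pf_v = fit_power_law(series[v])
                resid_v = Y[i] - pf_v.predict(grid)
                detrended = IndexedSeries(grid, resid_v)
                sel = lasso_select(detrended, cands, max_predictors, seed=seed)
                sel = _bic_prune(grid, resid_v, sel, basis_cols)
            else:
                sel = []
            fit = _fit_node(grid, Y[i], sel, smoothers, lop_order)
        except Exception as exc:
            logger.warning("node %s failed (%s); retained with no incoming edges", v, exc)
            try:
                pf = fit_power_law(series[v])
                a, b = pf.alpha, pf.beta
            except Exception:
                a, b = float(np.mean(Y[i])), 0.0
            curve = Y[i][0] + a * (grid ** b - grid[0] ** b)
            node_indep[v] = {"alpha": a, "beta": b, "curve": curve}
            node_mean[v] = curve
            continue
        node_indep[v] = {"alpha": fit["alpha"], "beta": fit["beta"],
                         "curve": fit["indep_curve"]}
        mean = fit["indep_curve"].copy()
        for u, curve in fit["dep_curves"].items():
            edges[(v, u)] = _edge_summary(grid, curve)
            mean = mean + curve
        node_mean[v] = mean

    net = SparseNetwork(node_ids=nodes, grid=grid, node_indep=node_indep,
                        edges=edges, node_mean=node_mean)
    net.hubness = {v: hubness(net, v) for v in nodes}
    return net


def hubness(network: SparseNetwork, node) -> float:
    """Outgoing hubness: sum over targets of |dep area| / target indep area."""
    if node not in network.node_ids:
        raise KeyError(node)
    total = 0.0
    for (t, s) in network.out_edges(node):
        dep = network.edges[(t, s)]["curve"]
        num = float(np.trapezoid(np.abs(dep), network.grid))
        den = float(np.trapezoid(network.node_indep[t]["curve"], network.grid))
        if abs(den) < 1e-12:
            logger.warning("target %s has zero independent integral; term skipped", t)
            continue
        total += num / den
    return total


def classify_network_roles(network: SparseNetwork) -> dict:
    """primary_hub: out>0, in=0; secondary_hub: out>0, in>0; else subordinate."""
    roles = {}
    for v in network.node_ids:
        out_deg = len(network.out_edges(v))
        in_deg = len(network.in_edges(v))
        if out_deg > 0 and in_deg == 0:
            roles[v] = "primary_hub"
        elif out_deg > 0:
            roles[v] = "secondary_hub"
        else:
            roles[v] = "subordinate"
    return roles


def module_network(table: ExpressionTable, assignment, stage_labels=None,
                   lop_order: int = DEFAULT_LOP_ORDER,
                   seed: int = 0, max_predictors: int = DEFAULT_MAX_PREDICTORS,
                   min_samples: int = 5) -> dict:
    """Stage- and group-specific module-level networks.

    Genes are collapsed to unweighted module-mean series per sample; a
    network is fit within each (stage x group) stratum.  Returns
    {(stage, group): SparseNetwork}; strata with fewer than ``min_samples``
    samples are skipped with a warning.
    """
    import pandas as pd

    labels = np.asarray(assignment.labels)
    if labels.size != table.shape[0]:
        raise ValueError("assignment does not cover all genes")
    modules = sorted(set(labels.tolist()))
    collapsed = pd.DataFrame(
        {f"M{k}": table.values.iloc[labels == k].mean(axis=0) for k in modules}).T
    meta = table.col_meta
    if meta is None:
        raise ValueError("module networks need column metadata")
    stages = stage_labels if stage_labels is not None else sorted(meta["stage"].unique())
    groups = sorted(meta["group_label"].unique())
    ei = table.values.sum(axis=0)  # per-sample EI over all genes

    out = {}
    for stage in stages:
        for group in groups:
            cols = [c for c in table.values.columns
                    if meta.loc[c, "stage"] == stage and meta.loc[c, "group_label"] == group]
            if len(cols) < min_samples:
                logger.warning("stratum (%s, %s) has %d samples; skipped",
                               stage, group, len(cols))
                continue
            sub = ExpressionTable(collapsed[cols])
            out[(stage, group)] = fit_network(
                sub, ei[cols].to_numpy(dtype=float),
                max_predictors=max_predictors, lop_order=lop_order, seed=seed)
    return out
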