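"""Quasi-dynamic ODE machinery.

A qdODE system evolves node states along an expression-derived index N (NI or
EI) rather than time.  Each node v obeys

    dg_v/dN = q_v(N) + sum_{u -> v} q_{v<-u}(g_u(N))

where the *independent* rate q_v is the index-derivative of a power curve
``alpha * N**beta`` (allometric part-whole scaling) and each *dependent* rate
q_{v<-u} is a Legendre-polynomial series in the source node's state.  The
integrals of the individual rate terms decompose a node's fitted trajectory
into an independent curve P plus one dependent curve per incoming edge; the
sign of a dependent curve says whether the source activates (+) or inhibits
(-) the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "LOPBasis", "QdodeSpec", "ComponentDecomposition",
    "lop_evaluate", "independent_rate", "dependent_rate",
    "solve_qdode", "decompose",
]

#: default number of RK4 sub-steps per full grid span
DEFAULT_SUBSTEPS = 100


def lop_evaluate(order_index: int, x: float | np.ndarray) -> float | np.ndarray:
    """Legendre polynomial P_r evaluated at x in [-1, 1] (Bonnet recurrence)."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1 + 1e-12):
        raise ValueError("x outside [-1, 1]")
    if order_index < 0:
        raise ValueError("order_index must be >= 0")
    p_prev = np.ones_like(x)
    if order_index == 0:
        return p_prev if p_prev.ndim else float(p_prev)
    p = x.copy()
    for r in range(1, order_index):
        p, p_prev = ((2 * r + 1) * x * p - r * p_prev) / (r + 1), p
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class LOPBasis:
    """Legendre basis of a given order on an affinely mapped domain.

    The dependent rate uses polynomial degrees 1..order (no constant term: a
    constant dependent rate is not identifiable against the independent power
    term).  ``domain`` is mapped affinely onto [-1, 1]; out-of-domain source
    values are clamped to the boundary.
    """

    order: int
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("basis order must be >= 1")
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError("domain must satisfy lo < hi")

    def map_to_unit(self, x: float | np.ndarray) -> float | np.ndarray:
        lo, hi = self.domain
        z = 2.0 * (np.asarray(x, dtype=float) - lo) / (hi - lo) - 1.0
        z = np.clip(z, -1.0, 1.0)
        return z if z.ndim else float(z)

    def design(self, x: np.ndarray) -> np.ndarray:
        """(len(x), order) matrix of P_1..P_order at the mapped points."""
        z = np.atleast_1d(np.asarray(self.map_to_unit(x), dtype=float))
        return np.column_stack([lop_evaluate(r, z) for r in range(1, self.order + 1)])


def independent_rate(alpha: float, beta: float, N: float | np.ndarray) -> float | np.ndarray:
    """Index-derivative of the power curve alpha * N**beta."""
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("index must be positive")
    out = alpha * beta * N ** (beta - 1.0)
    return out if out.ndim else float(out)


def dependent_rate(coeffs: np.ndarray, source_value: float | np.ndarray,
                   basis: LOPBasis) -> float | np.ndarray:
    """Legendre-series dependent rate evaluated at the source node's state."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        raise ValueError("empty coefficient vector")
    if coeffs.size != basis.order:
        raise ValueError("coefficient length must equal basis order")
    z = np.atleast_1d(np.asarray(basis.map_to_unit(source_value), dtype=float))
    out = np.zeros_like(z)
    for r in range(1, basis.order + 1):
        out += coeffs[r - 1] * lop_evaluate(r, z)
    return out if np.ndim(source_value) else float(out[0])


@dataclass
class QdodeSpec:
    """Parameterization of a qdODE system.

    ``independent`` maps node id -> (alpha, beta) of its power curve;
    ``edges`` maps (target, source) -> Legendre coefficient vector (absent
    pair = no edge); ``initial`` maps node id -> state at the smallest grid
    point.  ``lop`` may be a single shared basis or a per-edge dict.
    """

    node_ids: list
    independent: dict
    edges: dict
    lop: LOPBasis | dict
    initial: dict

    def __post_init__(self) -> None:
        for (t, s), c in self.edges.items():
            if t == s:
                raise ValueError("self-edges are not allowed")
            if t not in self.node_ids or s not in self.node_ids:
                raise ValueError(f"edge ({t}, {s}) references unknown node")
            basis = self.edge_basis(t, s)
            if len(np.asarray(c)) != basis.order:
                raise ValueError(f"edge ({t}, {s}): coefficient length != basis order")
        for v in self.node_ids:
            if v not in self.independent:
                raise ValueError(f"node {v} missing (alpha, beta)")
            if v not in self.initial:
                raise ValueError(f"node {v} missing initial value")

    def edge_basis(self, target, source) -> LOPBasis:
        if isinstance(self.lop, dict):
            return self.lop[(target, source)]
        return self.lop

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_json(self) -> str:
        basis = self.lop
        if isinstance(basis, dict):
            lop = {f"{t}<-{s}": {"order": b.order, "domain": list(b.domain)}
                   for (t, s), b in basis.items()}
        else:
            lop = {"order": basis.order, "domain": list(basis.domain)}
        return json.dumps({
            "node_ids": list(self.node_ids),
            "independent": {str(v): list(map(float, ab)) for v, ab in self.independent.items()},
            "edges": {f"{t}<-{s}": [float(c) for c in np.asarray(cv)]
                      for (t, s), cv in self.edges.items()},
            "lop": lop,
            "initial": {str(v): float(x) for v, x in self.initial.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "QdodeSpec":
        d = json.loads(text)

        def parse_key(k):
            t, s = k.split("<-")
            return t, s

        if "order" in d["lop"]:
            lop = LOPBasis(d["lop"]["order"], tuple(d["lop"]["domain"]))
        else:
            lop = {parse_key(k): LOPBasis(v["order"], tuple(v["domain"]))
                   for k, v in d["lop"].items()}
        return cls(
            node_ids=d["node_ids"],
            independent={v: tuple(ab) for v, ab in d["independent"].items()},
            edges={parse_key(k): np.asarray(v, dtype=float) for k, v in d["edges"].items()},
            lop=lop,
            initial=dict(d["initial"]),
        )


@dataclass
class ComponentDecomposition:
    """Fitted trajectories decomposed into independent + dependent curves.

    ``mean[v]`` is node v's trajectory on ``grid``; ``indep[v]`` the integral
    of its independent rate (starting at the initial value); ``dep[(t, s)]``
    the integral of edge t<-s's rate (starting at 0).  ``net_dep[(t, s)]`` is
    the dependent curve's value at the largest grid point — the signed net
    effect of s on t over the observed index range.
    """

    grid: np.ndarray
    mean: dict
    indep: dict
    dep: dict

    @property
    def net_dep(self) -> dict:
        return {e: float(curve[-1]) for e, curve in self.dep.items()}

    def indep_range(self, node) -> float:
        c = self.indep[node]
        return float(np.max(c) - np.min(c))


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D vector with >= 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] <= 0:
        raise ValueError("grid must be positive (power-law rates)")
    return grid


def _integrate(spec: QdodeSpec, grid: np.ndarray, substeps: int) -> ComponentDecomposition:
    """Coupled RK4 over the grid, accumulating each rate term's own integral.

    The state is the concatenation of every component curve (one independent
    integral per node, one dependent integral per edge); a node's trajectory
    is always the sum of its components, so conservation holds by
    construction up to integration error.
    """
    grid = _check_grid(grid)
    nodes = list(spec.node_ids)
    idx = {v: i for i, v in enumerate(nodes)}
    m = len(nodes)
    edges = list(spec.edges.items())
    ab = np.array([spec.independent[v] for v in nodes], dtype=float)
    init = np.array([spec.initial[v] for v in nodes], dtype=float)

    # per-edge precomputation
    e_target = np.array([idx[t] for (t, s), _ in edges], dtype=int)
    e_source = np.array([idx[s] for (t, s), _ in edges], dtype=int)
    e_coeffs = [np.asarray(c, dtype=float) for _, c in edges]
    e_basis = [spec.edge_basis(t, s) for (t, s), _ in edges]

    span = grid[-1] - grid[0]
    hmax = span / max(substeps, 1)

    def rates(N: float, indep_int: np.ndarray, dep_int: np.ndarray):
        g = indep_int.copy()
        np.add.at(g, e_target, dep_int)
        d_ind = ab[:, 0] * ab[:, 1] * N ** (ab[:, 1] - 1.0)
        d_dep = np.array([
            dependent_rate(e_coeffs[k], g[e_source[k]], e_basis[k])
            for k in range(len(edges))
        ]) if edges else np.empty(0)
        return d_ind, d_dep

    indep_int = init.copy()
    dep_int = np.zeros(len(edges))
    indep_curves = np.empty((m, grid.size))
    dep_curves = np.empty((len(edges), grid.size))
    indep_curves[:, 0] = indep_int
    dep_curves[:, 0] = dep_int

    for i in range(grid.size - 1):
        a, b = grid[i], grid[i + 1]
        nsub = max(1, int(np.ceil((b - a) / hmax)))
        h = (b - a) / nsub
        N = a
        for _ in range(nsub):
            k1i, k1d = rates(N, indep_int, dep_int)
            k2i, k2d = rates(N + h / 2, indep_int + h / 2 * k1i, dep_int + h / 2 * k1d)
            k3i, k3d = rates(N + h / 2, indep_int + h / 2 * k2i, dep_int + h / 2 * k2d)
            k4i, k4d = rates(N + h, indep_int + h * k3i, dep_int + h * k3d)
            indep_int = indep_int + h / 6 * (k1i + 2 * k2i + 2 * k3i + k4i)
            dep_int = dep_int + h / 6 * (k1d + 2 * k2d + 2 * k3d + k4d)
            N += h
        if not (np.all(np.isfinite(indep_int)) and np.all(np.isfinite(dep_int))):
            raise FloatingPointError(f"non-finite state at grid point {i + 1} (N={b:g})")
        indep_curves[:, i + 1] = indep_int
        dep_curves[:, i + 1] = dep_int

    mean = {}
    for v in nodes:
        mean[v] = indep_curves[idx[v]].copy()
    for k, ((t, s), _) in enumerate(edges):
        mean[t] = mean[t] + dep_curves[k]
    return ComponentDecomposition(
        grid=grid,
        mean=mean,
        indep={v: indep_curves[idx[v]] for v in nodes},
        dep={e: dep_curves[k] for k, (e, _) in enumerate(edges)},
    )


def solve_qdode(spec: QdodeSpec, grid: np.ndarray,
                substeps: int = DEFAULT_SUBSTEPS) -> dict:
    """Integrate the coupled system; returns node id -> trajectory on grid."""
    return _integrate(spec, grid, substeps).mean


def decompose(spec: QdodeSpec, grid: np.ndarray,
              substeps: int = DEFAULT_SUBSTEPS) -> ComponentDecomposition:
    """Integrate while accumulating per-term integrals (P and P-arrow curves)."""
    return _integrate(spec, grid, substeps)


def power_curve(alpha: float, beta: float, N: np.ndarray) -> np.ndarray:
    """The allometric power curve alpha * N**beta."""
    return alpha * np.asarray(N, dtype=float) ** beta


def legendre_coeffs_to_standard(coeffs: np.ndarray) -> np.ndarray:
    """Convert degrees-1..r Legendre coefficients to a standard polynomial.

    Utility for tests and serialization; uses numpy's Legendre module.
    """
    c = np.concatenate([[0.0], np.asarray(coeffs, dtype=float)])
    return npleg.leg2poly(c)
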