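"""Synthetic data generation from qdODE game models.

The generator emulates the sampling design the model targets: paired
two-cell-type expression of a gene across n units (default sample sizes 15
and 50), produced by solving a two-node qdODE along a niche-index grid and
adding zero-mean Gaussian noise with bivariate AR(1) structure, plus an
m-node variant for network-recovery experiments.  Pairwise defaults produce
two visibly different increasing power trajectories with signed couplings;
network defaults mix increasing and decreasing nodes, the qualitative
shapes of processed expression against the NI/EI axes.  The defaults are
the documented study conditions (see docs/methods.md) and are deliberately
stable across releases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import PairedGeneProfile
from .likelihood import AR1Params, build_ar1_covariance
from .ode import ComponentDecomposition, LOPBasis, QdodeSpec, decompose

logger = logging.getLogger(__name__)

#: default niche-index span of the latent grid
DEFAULT_NI_RANGE = (2.0, 12.0)

#: default two-node power parameters: node 1 (e.g. FGC) below node 2 (soma),
#: chosen so the total rate is near 1 and the self-consistent NI mode is
#: well-behaved
DEFAULT_AB1 = (0.25, 1.4)
DEFAULT_AB2 = (0.8, 0.7)

#: base Legendre coefficient shape for one directed edge (scaled by strength)
BASE_EDGE_SHAPE = np.array([0.25, -0.5, 0.45])


def default_pair_spec(strength_12: float = 0.0, strength_21: float = 0.0,
                      lop_order: int = 3,
                      ab1: tuple = DEFAULT_AB1, ab2: tuple = DEFAULT_AB2,
                      ni_range: tuple = DEFAULT_NI_RANGE) -> QdodeSpec:
    """A two-node game spec with signed coupling strengths.

    ``strength_12`` scales the soma->FGC (1<-2) edge, ``strength_21`` the
    FGC->soma edge; zero means the edge is absent.  Edge basis domains cover
    the source's noise-free power-curve range over the NI span.
    """
    lo, hi = ni_range
    shape = BASE_EDGE_SHAPE[:lop_order].copy()
    if lop_order > BASE_EDGE_SHAPE.size:
        shape = np.concatenate([shape, np.zeros(lop_order - BASE_EDGE_SHAPE.size)])
    edges, lop = {}, {}

    def dom(ab):
        vals = ab[0] * np.array([lo, hi]) ** ab[1]
        pad = 0.6 * (vals.max() - vals.min()) + 0.1
        return (vals.min() - pad, vals.max() + pad)

    if strength_12 != 0.0:
        edges[("n1", "n2")] = strength_12 * shape
        lop[("n1", "n2")] = LOPBasis(lop_order, dom(ab2))
    if strength_21 != 0.0:
        edges[("n2", "n1")] = strength_21 * shape
        lop[("n2", "n1")] = LOPBasis(lop_order, dom(ab1))
    if not lop:
        lop = LOPBasis(lop_order, dom(ab1))
    return QdodeSpec(
        node_ids=["n1", "n2"],
        independent={"n1": tuple(ab1), "n2": tuple(ab2)},
        edges=edges,
        lop=lop if isinstance(lop, LOPBasis) else lop,
        initial={"n1": ab1[0] * lo ** ab1[1], "n2": ab2[0] * lo ** ab2[1]},
    )


@dataclass
class PairTruth:
    """Generating truth accompanying a simulated paired profile."""

    spec: QdodeSpec
    ar1: AR1Params
    grid: np.ndarray          # NI values of the noise-free data, ascending
    mean1: np.ndarray
    mean2: np.ndarray
    decomposition: ComponentDecomposition
    mode: str
    consistency_gap: float    # max |grid - noisefree total| achieved
    net_dep: dict = field(default_factory=dict)


def _draw_grid(rng: np.random.Generator, n: int, lo: float, hi: float,
               log_uniform: bool) -> np.ndarray:
    if log_uniform:
        pts = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n - 1))
    else:
        pts = rng.uniform(lo, hi, size=n - 1)
    grid = np.sort(np.concatenate([[lo], pts]))
    # enforce strict increase
    span = hi - lo
    for i in range(1, n):
        if grid[i] - grid[i - 1] < 1e-6 * span:
            grid[i] = grid[i - 1] + 1e-6 * span
    return grid


def simulate_pairwise(spec: QdodeSpec, ar1: AR1Params, n: int, seed: int = 0,
                      *, ni_mode: str = "independent",
                      ni_range: tuple | None = None
                      ) -> tuple[PairedGeneProfile, PairTruth]:
    """Simulate one gene's paired expression from a two-node qdODE.

    ``ni_mode="independent"`` (default) draws the index grid, solves the
    qdODE on it and adds noise, treating the index as *given*: the profile
    carries the generating grid itself (``n_is_sum=False``), mirroring a
    simulation protocol where expression is generated at known NI values
    and refit.  ``ni_mode="consistent"`` instead labels the index with the
    noise-free totals so the generated NI equals g1+g2 (a monotone
    reparameterization of the latent axis) and the profile's NI is the
    noisy pair sum, as in real-data processing.  The truth record reports
    which mode produced the data and the residual consistency gap.
    """
    if len(spec.node_ids) != 2:
        raise ValueError("simulate_pairwise needs a 2-node spec")
    if n < 5:
        raise ValueError("n must be >= 5")
    rng = np.random.default_rng(seed)
    v1, v2 = spec.node_ids
    # the grid starts exactly at the range's lower bound, where the spec's
    # initial values are defined
    lo, hi = DEFAULT_NI_RANGE if ni_range is None else ni_range

    latent = _draw_grid(rng, n, lo, hi, log_uniform=False)
    dec = decompose(spec, latent)
    mean1, mean2 = dec.mean[v1], dec.mean[v2]
    totals = mean1 + mean2
    if ni_mode == "consistent":
        # relabel the index as the noise-free totals: the generated NI then
        # equals g1+g2 exactly (the defining property of the niche index)
        if np.any(np.diff(totals) <= 0):
            raise RuntimeError("noise-free totals not monotone increasing; "
                               "weaken the couplings or use ni_mode='independent'")
        grid = totals.copy()
        dec.grid = grid
        gap = 0.0
    elif ni_mode == "independent":
        grid = latent
        gap = float(np.max(np.abs(totals - grid)))
    else:
        raise ValueError(f"unknown ni_mode {ni_mode!r}")

    cov = build_ar1_covariance(ar1, n)
    noise = rng.multivariate_normal(np.zeros(2 * n), cov, method="cholesky")
    y1 = np.clip(mean1 + noise[:n], 0.0, None)
    y2 = np.clip(mean2 + noise[n:], 0.0, None)

    if ni_mode == "independent":
        profile = PairedGeneProfile("sim", y1, y2, N=grid,
                                    unit_ids=list(range(n)), n_is_sum=False)
    else:
        profile = PairedGeneProfile("sim", y1, y2, unit_ids=list(range(n)))
    truth = PairTruth(spec=spec, ar1=ar1, grid=grid, mean1=mean1, mean2=mean2,
                      decomposition=dec, mode=ni_mode, consistency_gap=gap,
                      net_dep=dec.net_dep)
    return profile, truth


def simulate_null(ab1: tuple = DEFAULT_AB1, ab2: tuple = DEFAULT_AB2,
                  ar1: AR1Params | None = None, n: int = 15, seed: int = 0,
                  **kwargs) -> tuple[PairedGeneProfile, PairTruth]:
    """Simulate from the non-game model: independent power curves only."""
    spec = default_pair_spec(0.0, 0.0, ab1=ab1, ab2=ab2)
    if ar1 is None:
        ar1 = default_ar1()
    return simulate_pairwise(spec, ar1, n, seed, **kwargs)


def default_ar1(noise_scale: float = 1.0) -> AR1Params:
    """Moderate-noise AR(1) defaults: sd about 1% of the default signal span
    (the observations emulate subpopulation means, which average away most
    single-cell noise)."""
    return AR1Params(sigma1=0.05 * noise_scale, sigma2=0.06 * noise_scale,
                     rho1=0.3, rho2=0.3, rho12=0.2)


def simulate_network(m: int, regulators_per_node: int, coupling_scale: float,
                     n: int, seed: int = 0, *, lop_order: int = 3,
                     noise_sd: float = 0.02, noise_rho: float = 0.3,
                     ei_range: tuple = (5.0, 50.0), max_retries: int = 5,
                     dynamics: str = "conditional"):
    """Simulate an m-gene expression table from a sparse qdODE network.

    Each node gets exactly ``regulators_per_node`` incoming edges with random
    signs, Legendre coefficients scaled by ``coupling_scale``.  Gaussian
    AR(1) noise (sd = ``noise_sd`` times each node's trajectory span) is
    added per node.  Returns ``(table, index, truth)`` where ``table`` is a
    genes x samples :class:`~qdgame.data.ExpressionTable`, ``index`` the
    ascending EI grid and ``truth`` the generating spec plus decomposition.

    ``dynamics="conditional"`` (default) generates the table as the fixed
    point of the sparse regression decomposition itself: every node equals
    its power curve plus the Legendre dependent integrals of its regulators'
    *observed* series plus noise — the exact data-generating process the
    decoupled network estimator formalizes.  ``dynamics="coupled"``
    integrates the joint m-dimensional ODE instead (noise-free trajectories
    driven by model states); its regulator identities are only weakly
    identifiable because smooth monotone sources are mutually
    near-collinear as regressors.
    """
    from .data import ExpressionTable
    import pandas as pd

    if m < 2:
        raise ValueError("m must be >= 2")
    if not 0 <= regulators_per_node < m:
        raise ValueError("regulators_per_node must be in [0, m)")
    rng = np.random.default_rng(seed)
    lo, hi = ei_range
    grid = _draw_grid(rng, n, lo, hi, log_uniform=False)
    nodes = [f"g{j + 1}" for j in range(m)]

    shape = BASE_EDGE_SHAPE[:lop_order].copy()
    if lop_order > BASE_EDGE_SHAPE.size:
        shape = np.concatenate([shape, np.zeros(lop_order - BASE_EDGE_SHAPE.size)])

    # a share of nodes decreases with the index (as real modules do in one
    # cell type but not the other); opposite traversal directions are what
    # make regulator identities distinguishable downstream
    def draw_ab():
        if rng.random() < 0.35:
            beta = rng.uniform(-0.9, -0.3)
            alpha = rng.uniform(3.0, 12.0)
        else:
            beta = rng.uniform(0.4, 1.6)
            alpha = rng.uniform(0.3, 1.5)
        return alpha, beta
    ab = {v: draw_ab() for v in nodes}

    def build_edges(scale: float):
        edges, lop = {}, {}
        rng_e = np.random.default_rng(seed + 1)
        for v in nodes:
            others = [u for u in nodes if u != v]
            sources = rng_e.choice(others, size=regulators_per_node, replace=False)
            for u in sources:
                sign = 1.0 if rng_e.random() < 0.5 else -1.0
                wiggle = 1.0 + 0.3 * rng_e.standard_normal(lop_order)
                if scale != 0.0:
                    edges[(v, str(u))] = sign * scale * shape * wiggle
                    a, b = ab[str(u)]
                    vals = a * np.array([lo, hi]) ** b
                    # tight domains match the fitting convention (observed
                    # source range maps onto the full basis interval)
                    pad = 0.05 * (vals.max() - vals.min()) + 0.02
                    lop[(v, str(u))] = LOPBasis(lop_order, (vals.min() - pad, vals.max() + pad))
        return edges, lop

    def ar1_noise(sd: float) -> np.ndarray:
        e = np.empty(n)
        e[0] = rng.standard_normal() * sd
        fac = np.sqrt(1 - noise_rho ** 2)
        for i in range(1, n):
            e[i] = noise_rho * e[i - 1] + fac * sd * rng.standard_normal()
        return e

    power = {v: ab[v][0] * grid ** ab[v][1] for v in nodes}

    if dynamics == "conditional":
        from .network import _basis_integrals

        edges, lop = build_edges(coupling_scale if coupling_scale != 0 else 1.0)
        if coupling_scale == 0.0:
            edges, lop = {}, {}
        noise = {v: ar1_noise(noise_sd * max(np.ptp(power[v]), 1e-6))
                 for v in nodes}
        # rescale each edge so its dependent curve's amplitude is a fixed
        # fraction of the target's power span, scaled by coupling_scale
        y = {v: power[v] + noise[v] for v in nodes}
        coeffs = {}
        for (t, s), c in edges.items():
            B0 = _basis_integrals(grid, lambda N, u=s: np.interp(N, grid, y[u]),
                                  lop[(t, s)])
            amp = float(np.max(np.abs(B0 @ c)))
            target_amp = 0.25 * abs(coupling_scale) * max(np.ptp(power[t]), 1e-6)
            coeffs[(t, s)] = c * (target_amp / amp) if amp > 1e-12 else c
        dep_curves = {e: np.zeros(n) for e in coeffs}
        for _ in range(8):
            B = {(t, s): _basis_integrals(
                    grid, lambda N, u=s: np.interp(N, grid, y[u]), lop[(t, s)])
                 for (t, s) in coeffs}
            dep_curves = {e: B[e] @ coeffs[e] for e in coeffs}
            y_new = {}
            for v in nodes:
                y_new[v] = power[v] + noise[v] + sum(
                    dep_curves[e] for e in coeffs if e[0] == v)
            shift = max((np.max(np.abs(y_new[v] - y[v])) for v in nodes),
                        default=0.0)
            y = y_new
            if shift < 1e-10:
                break
        values = np.array([np.clip(y[v], 0.0, None) for v in nodes])
        spec = QdodeSpec(
            node_ids=nodes, independent=ab, edges=coeffs,
            lop=lop if lop else LOPBasis(lop_order, (0.0, 1.0)),
            initial={v: power[v][0] for v in nodes},
        )
        mean = {v: y[v] - noise[v] for v in nodes}
        dec = ComponentDecomposition(grid=grid, mean=mean,
                                     indep=power, dep=dep_curves)
        scale = coupling_scale
    elif dynamics == "coupled":
        scale = coupling_scale
        for attempt in range(max_retries):
            edges, lop = build_edges(scale)
            spec = QdodeSpec(
                node_ids=nodes,
                independent=ab,
                edges=edges,
                lop=lop if lop else LOPBasis(lop_order, (0.0, 1.0)),
                initial={v: power[v][0] for v in nodes},
            )
            try:
                dec = decompose(spec, grid)
                if all(np.all(np.isfinite(c)) for c in dec.mean.values()):
                    break
            except FloatingPointError:
                pass
            scale *= 0.5
            logger.warning("non-finite network trajectory; damping coupling to %.3g",
                           scale)
        else:
            raise RuntimeError("could not produce finite trajectories")
        values = np.empty((m, n))
        for j, v in enumerate(nodes):
            sd = noise_sd * max(np.ptp(dec.mean[v]), 1e-6)
            values[j] = np.clip(dec.mean[v] + ar1_noise(sd), 0.0, None)
    else:
        raise ValueError(f"unknown dynamics {dynamics!r}")

    table = ExpressionTable(pd.DataFrame(
        values, index=nodes, columns=[f"s{i + 1}" for i in range(n)]))
    truth = {
        "spec": spec,
        "decomposition": dec,
        "grid": grid,
        "dynamics": dynamics,
        "edges": {e: {"sign": int(np.sign(dec.net_dep[e])) if dec.net_dep[e] != 0 else 0,
                      "net_dep": dec.net_dep[e]}
                  for e in spec.edges},
        "coupling_scale": scale,
    }
    return table, grid, truth
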