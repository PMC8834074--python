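"""Compiled kernels for the pairwise qdODE maximum-likelihood fit.

The permutation likelihood-ratio test refits the two-node qdODE model for
every permutation replicate, which means tens of thousands of optimizations
each wrapping an RK4 integration and an AR(1) Gaussian log-likelihood.
These inner loops are compiled with numba; the public surface in
:mod:`qdgame.likelihood` wraps them and is cross-checked in the test suite
against plain numpy/scipy implementations of the same quantities.

Parameter conventions (unconstrained transforms):

* ``theta9 = [log a1, b1, log a2, b2, log s1, log s2, atanh r1, atanh r2,
  atanh r12]`` — power and AR(1) parameters;
* ``theta_full`` (9 + 2r) inserts the edge coefficient vectors ``c_{1<-2}``
  and ``c_{2<-1}`` after the four power parameters.

Objective modes: 0 = null (no edges, theta9); 1 = full (theta_full);
2 = full with the edge coefficients held fixed at ``cfix`` (theta9).

The full-model optimizer in :mod:`qdgame.likelihood` alternates a
generalized-least-squares update of the edge coefficients (the RK4 kernel
also accumulates the per-basis-term integrals along the current trajectory,
making the mean locally linear in the coefficients) with Nelder-Mead moves
of the remaining parameters, then polishes all parameters jointly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e12
#: bounds keeping the AR(1) covariance away from singularity during fitting
RHO_MAX = 0.99
RHO12_MAX = 0.95


@njit(cache=True, fastmath=True)
def _leg_all(z, out):
    """P_1..P_r at z (Bonnet recurrence); out has length r."""
    r = out.shape[0]
    p_prev = 1.0
    p = z
    out[0] = p
    for j in range(1, r):
        p_next = ((2 * j + 1) * z * p - j * p_prev) / (j + 1)
        p_prev = p
        p = p_next
        out[j] = p


@njit(cache=True, fastmath=True)
def _clamp_unit(x, lo, hi):
    z = 2.0 * (x - lo) / (hi - lo) - 1.0
    if z > 1.0:
        return 1.0
    if z < -1.0:
        return -1.0
    return z


@njit(cache=True, fastmath=True)
def _pair_mean_basis(grid, a1, b1, a2, b2, c12, c21, dom1, dom2,
                     init1, init2, substeps):
    """Coupled two-node RK4 accumulating per-basis-term integrals.

    Returns (mu1, mu2, B12, B21): the mean trajectories and, per grid point,
    the cumulative integrals of each Legendre term of edge 1<-2 (argument:
    node 2's model state, domain ``dom2``) and edge 2<-1.  The dependent
    curves are ``B12 @ c12`` and ``B21 @ c21``; the independent integrals
    are ``mu - dep``.  ``c12``/``c21`` may be all zero; their length r sets
    the basis order (r = 0 disables an edge).
    """
    n = grid.shape[0]
    r12 = c12.shape[0]
    r21 = c21.shape[0]
    mu1 = np.empty(n)
    mu2 = np.empty(n)
    B12 = np.zeros((n, r12))
    B21 = np.zeros((n, r21))
    i1 = init1
    i2 = init2
    b12 = np.zeros(r12)
    b21 = np.zeros(r21)
    p12 = np.empty(r12)
    p21 = np.empty(r21)
    mu1[0] = i1
    mu2[0] = i2
    span = grid[n - 1] - grid[0]
    hmax = span / substeps
    # stage buffers
    s_b12 = np.empty(r12)
    s_b21 = np.empty(r21)
    acc_b12 = np.empty(r12)
    acc_b21 = np.empty(r21)
    k_b12 = np.empty((4, r12))
    k_b21 = np.empty((4, r21))
    for i in range(n - 1):
        a = grid[i]
        b = grid[i + 1]
        nsub = int(np.ceil((b - a) / hmax))
        if nsub < 1:
            nsub = 1
        h = (b - a) / nsub
        N = a
        for _ in range(nsub):
            s_i1 = i1
            s_i2 = i2
            for q in range(r12):
                s_b12[q] = b12[q]
                acc_b12[q] = 0.0
            for q in range(r21):
                s_b21[q] = b21[q]
                acc_b21[q] = 0.0
            acc_i1 = 0.0
            acc_i2 = 0.0
            for stage in range(4):
                if stage == 0:
                    Ns = N
                    w = 1.0
                elif stage == 3:
                    Ns = N + h
                    w = 1.0
                else:
                    Ns = N + 0.5 * h
                    w = 2.0
                k_i1 = a1 * b1 * Ns ** (b1 - 1.0)
                k_i2 = a2 * b2 * Ns ** (b2 - 1.0)
                # model states include the dependent parts
                d12 = 0.0
                for q in range(r12):
                    d12 += s_b12[q] * c12[q]
                d21 = 0.0
                for q in range(r21):
                    d21 += s_b21[q] * c21[q]
                g1 = s_i1 + d12
                g2 = s_i2 + d21
                if r12 > 0:
                    z2 = _clamp_unit(g2, dom2[0], dom2[1])
                    _leg_all(z2, p12)
                if r21 > 0:
                    z1 = _clamp_unit(g1, dom1[0], dom1[1])
                    _leg_all(z1, p21)
                acc_i1 += w * k_i1
                acc_i2 += w * k_i2
                for q in range(r12):
                    acc_b12[q] += w * p12[q]
                    k_b12[stage, q] = p12[q]
                for q in range(r21):
                    acc_b21[q] += w * p21[q]
                    k_b21[stage, q] = p21[q]
                if stage < 3:
                    fac = 0.5 * h if stage < 2 else h
                    s_i1 = i1 + fac * k_i1
                    s_i2 = i2 + fac * k_i2
                    for q in range(r12):
                        s_b12[q] = b12[q] + fac * k_b12[stage, q]
                    for q in range(r21):
                        s_b21[q] = b21[q] + fac * k_b21[stage, q]
            i1 += h / 6.0 * acc_i1
            i2 += h / 6.0 * acc_i2
            for q in range(r12):
                b12[q] += h / 6.0 * acc_b12[q]
            for q in range(r21):
                b21[q] += h / 6.0 * acc_b21[q]
            N += h
        d12 = 0.0
        for q in range(r12):
            B12[i + 1, q] = b12[q]
            d12 += b12[q] * c12[q]
        d21 = 0.0
        for q in range(r21):
            B21[i + 1, q] = b21[q]
            d21 += b21[q] * c21[q]
        mu1[i + 1] = i1 + d12
        mu2[i + 1] = i2 + d21
    return mu1, mu2, B12, B21


@njit(cache=True, fastmath=True)
def _ar1_cov(n, s1, s2, r1, r2, r12):
    """2n x 2n bivariate AR(1) covariance (block order: type 1 then type 2)."""
    C = np.empty((2 * n, 2 * n))
    prod = r1 * r2
    u = np.sqrt(np.abs(prod))
    if prod < 0.0:
        u = -u
    cx = r12 * s1 * s2
    for i in range(n):
        for j in range(n):
            d = i - j
            if d < 0:
                d = -d
            C[i, j] = s1 * s1 * r1 ** d
            C[n + i, n + j] = s2 * s2 * r2 ** d
            C[i, n + j] = cx * u ** d
            C[n + i, j] = cx * u ** d
    return C


@njit(cache=True, fastmath=True)
def _chol(A):
    """Lower Cholesky with a positive-definiteness flag."""
    n = A.shape[0]
    L = np.zeros((n, n))
    for j in range(n):
        s = A[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s <= 1e-300:
            return L, False
        L[j, j] = np.sqrt(s)
        inv = 1.0 / L[j, j]
        for i in range(j + 1, n):
            t = A[i, j]
            for k in range(j):
                t -= L[i, k] * L[j, k]
            L[i, j] = t * inv
    return L, True


@njit(cache=True, fastmath=True)
def _mvn_nll(resid, C):
    """Negative log N(resid; 0, C); BIG when C is not positive definite."""
    d = resid.shape[0]
    L, ok = _chol(C)
    if not ok:
        return BIG
    logdet = 0.0
    for i in range(d):
        logdet += np.log(L[i, i])
    q = 0.0
    z = np.empty(d)
    for i in range(d):
        t = resid[i]
        for k in range(i):
            t -= L[i, k] * z[k]
        z[i] = t / L[i, i]
        q += z[i] * z[i]
    return 0.5 * d * np.log(2.0 * np.pi) + logdet + 0.5 * q


@njit(cache=True)
def _clip(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


@njit(cache=True, fastmath=True)
def _neg_loglik(theta, mode, r, cfix, grid, y1, y2, dom1, dom2, substeps):
    """Negative log-likelihood; see module docstring for modes and layouts."""
    n = grid.shape[0]
    a1 = np.exp(_clip(theta[0], -25.0, 25.0))
    b1 = _clip(theta[1], -12.0, 12.0)
    a2 = np.exp(_clip(theta[2], -25.0, 25.0))
    b2 = _clip(theta[3], -12.0, 12.0)
    if mode == 1:
        c12 = theta[4:4 + r].copy()
        c21 = theta[4 + r:4 + 2 * r].copy()
        off = 4 + 2 * r
    elif mode == 2:
        c12 = cfix[:r].copy()
        c21 = cfix[r:].copy()
        off = 4
    else:
        c12 = np.empty(0)
        c21 = np.empty(0)
        off = 4
    s1 = np.exp(_clip(theta[off], -20.0, 8.0))
    s2 = np.exp(_clip(theta[off + 1], -20.0, 8.0))
    # correlations bounded away from 1: NI-indexed pairs have a near-
    # deterministic residual sum (N = y1 + y2), which would otherwise push
    # the covariance to singularity and make the likelihood unbounded
    r1 = RHO_MAX * np.tanh(_clip(theta[off + 2], -7.0, 7.0))
    r2 = RHO_MAX * np.tanh(_clip(theta[off + 3], -7.0, 7.0))
    r12 = RHO12_MAX * np.tanh(_clip(theta[off + 4], -7.0, 7.0))

    mu1, mu2, _, _ = _pair_mean_basis(grid, a1, b1, a2, b2, c12, c21,
                                      dom1, dom2, y1[0], y2[0], substeps)
    for i in range(n):
        if not (np.isfinite(mu1[i]) and np.isfinite(mu2[i])):
            return BIG
    resid = np.empty(2 * n)
    for i in range(n):
        resid[i] = y1[i] - mu1[i]
        resid[n + i] = y2[i] - mu2[i]
    C = _ar1_cov(n, s1, s2, r1, r2, r12)
    nll = _mvn_nll(resid, C)
    if not np.isfinite(nll):
        return BIG
    # soft barrier keeping the correlation transforms off the singular
    # boundary (small samples otherwise overfit the covariance)
    for j in range(3):
        z = np.abs(theta[off + 2 + j])
        if z > 2.0:
            nll += 0.5 * (z - 2.0) ** 2
    return nll


@njit(cache=True, fastmath=True)
def _nelder_mead(x0, step, mode, r, cfix, grid, y1, y2, dom1, dom2, substeps,
                 maxiter, ftol):
    """Standard Nelder-Mead on _neg_loglik; returns (x_best, f_best, nfev)."""
    d = x0.shape[0]
    np_ = d + 1
    sim = np.empty((np_, d))
    fs = np.empty(np_)
    for i in range(np_):
        for j in range(d):
            sim[i, j] = x0[j]
        if i > 0:
            sim[i, i - 1] += step[i - 1]
        fs[i] = _neg_loglik(sim[i], mode, r, cfix, grid, y1, y2, dom1, dom2,
                            substeps)
    nfev = np_
    for _ in range(maxiter):
        order = np.argsort(fs)
        sim = sim[order]
        fs = fs[order]
        if fs[np_ - 1] - fs[0] <= ftol * (np.abs(fs[0]) + ftol):
            break
        cen = np.zeros(d)
        for i in range(np_ - 1):
            for j in range(d):
                cen[j] += sim[i, j]
        cen /= (np_ - 1)
        xr = 2.0 * cen - sim[np_ - 1]
        fr = _neg_loglik(xr, mode, r, cfix, grid, y1, y2, dom1, dom2, substeps)
        nfev += 1
        if fr < fs[0]:
            xe = cen + 2.0 * (cen - sim[np_ - 1])
            fe = _neg_loglik(xe, mode, r, cfix, grid, y1, y2, dom1, dom2,
                             substeps)
            nfev += 1
            if fe < fr:
                sim[np_ - 1] = xe
                fs[np_ - 1] = fe
            else:
                sim[np_ - 1] = xr
                fs[np_ - 1] = fr
        elif fr < fs[np_ - 2]:
            sim[np_ - 1] = xr
            fs[np_ - 1] = fr
        else:
            if fr < fs[np_ - 1]:
                xc = cen + 0.5 * (xr - cen)
            else:
                xc = cen + 0.5 * (sim[np_ - 1] - cen)
            fc = _neg_loglik(xc, mode, r, cfix, grid, y1, y2, dom1, dom2,
                             substeps)
            nfev += 1
            if fc < min(fr, fs[np_ - 1]):
                sim[np_ - 1] = xc
                fs[np_ - 1] = fc
            else:
                for i in range(1, np_):
                    for j in range(d):
                        sim[i, j] = sim[0, j] + 0.5 * (sim[i, j] - sim[0, j])
                    fs[i] = _neg_loglik(sim[i], mode, r, cfix, grid, y1, y2,
                                        dom1, dom2, substeps)
                nfev += np_ - 1
    ibest = np.argmin(fs)
    return sim[ibest].copy(), fs[ibest], nfev


@njit(cache=True)
def _gls_coeffs(B12, B21, r0_1, r0_2, C):
    """GLS edge coefficients: argmin over c of the Gaussian quadratic form.

    The mean residual is [r0_1 - B12 c12; r0_2 - B21 c21]; solves the
    normal equations in the C^-1 metric.  Returns (c, ok).
    """
    n = r0_1.shape[0]
    p1 = B12.shape[1]
    p2 = B21.shape[1]
    p = p1 + p2
    L, ok = _chol(C)
    if not ok:
        return np.zeros(p), False
    # whiten columns of X = [[B12, 0], [0, B21]] and the residual
    m = 2 * n
    W = np.zeros((m, p + 1))
    for i in range(n):
        for q in range(p1):
            W[i, q] = B12[i, q]
        for q in range(p2):
            W[n + i, p1 + q] = B21[i, q]
        W[i, p] = r0_1[i]
        W[n + i, p] = r0_2[i]
    # forward solve L Z = W
    for col in range(p + 1):
        for i in range(m):
            t = W[i, col]
            for k in range(i):
                t -= L[i, k] * W[k, col]
            W[i, col] = t / L[i, i]
    G = np.zeros((p, p))
    h = np.zeros(p)
    for a in range(p):
        for b in range(a, p):
            s = 0.0
            for i in range(m):
                s += W[i, a] * W[i, b]
            G[a, b] = s
            G[b, a] = s
        s = 0.0
        for i in range(m):
            s += W[i, a] * W[i, p]
        h[a] = s
    for a in range(p):
        G[a, a] += 1e-10
    Lg, okg = _chol(G)
    if not okg:
        return np.zeros(p), False
    # solve G c = h via Lg
    z = np.empty(p)
    for i in range(p):
        t = h[i]
        for k in range(i):
            t -= Lg[i, k] * z[k]
        z[i] = t / Lg[i, i]
    c = np.empty(p)
    for i in range(p - 1, -1, -1):
        t = z[i]
        for k in range(i + 1, p):
            t -= Lg[k, i] * c[k]
        c[i] = t / Lg[i, i]
    return c, True
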