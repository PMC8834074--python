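"""Allometric power-law fitting and power-curve functional clustering.

A gene's expression in one cell type scales with the total (NI or EI) as a
part-whole power law ``y = alpha * x**beta``.  ``fit_power_law`` estimates
(alpha, beta) by nonlinear least squares on the original scale, initialized
from log-log OLS.  ``functional_cluster`` groups genes whose EI-indexed
expression follows similar power curves using an EM-fitted mixture whose
component means are power curves (one per group per module) with Gaussian
residuals; ``select_module_count`` picks the module count by AIC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data import ExpressionTable, IndexedSeries

logger = logging.getLogger(__name__)


@dataclass
class PowerLawFit:
    """Fitted power curve y = alpha * x**beta with goodness-of-fit summaries."""

    alpha: float
    beta: float
    sse: float
    r2: float
    p_value: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.alpha * np.asarray(x, dtype=float) ** self.beta


def _loglog_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(alpha, beta, p) from OLS on (log x, log y); zeros in y are offset."""
    y_adj = y.copy()
    if (y_adj <= 0).any():
        pos = y_adj[y_adj > 0]
        offset = 0.5 * pos.min() if pos.size else 1.0
        y_adj = y_adj + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        ly = np.log(y_adj)
    if not np.all(np.isfinite(ly)):
        # fall back to a flat curve through the mean magnitude
        return max(float(np.mean(np.abs(y_adj))), 1e-8), 0.0, 1.0
    res = stats.linregress(np.log(x), ly)
    alpha = float(np.exp(res.intercept))
    beta = float(res.slope)
    pval = float(res.pvalue)
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        return max(float(np.mean(np.abs(y_adj))), 1e-8), 0.0, 1.0
    return alpha, beta, pval


def fit_power_law(series: IndexedSeries, weights: np.ndarray | None = None) -> PowerLawFit:
    """Least-squares fit of y = alpha * x**beta on the original scale.

    Initialized by OLS on (log x, log y); the reported p-value is the
    significance of the log-log slope.  Zeros in y only affect the
    initialization (they are offset by half the smallest positive value);
    the final original-scale fit sees the raw data.
    """
    x = np.asarray(series.index, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if x.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("index is constant")
    if np.any(x <= 0):
        raise ValueError("index must be positive")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    a0, b0, pval = _loglog_init(x, y)
    a0 = max(a0, 1e-12)

    def resid(theta):
        la, b = theta
        return sw * (np.exp(la) * x ** b - y)

    sol = optimize.least_squares(resid, x0=[np.log(a0), b0], method="lm",
                                 xtol=1e-12, ftol=1e-12)
    alpha, beta = float(np.exp(sol.x[0])), float(sol.x[1])
    fitted = alpha * x ** beta
    sse = float(np.sum(w * (y - fitted) ** 2))
    tss = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    return PowerLawFit(alpha, beta, sse, r2, pval)


@dataclass
class ModuleAssignment:
    """Hard module labels from power-curve functional clustering.

    ``module_fits[k][g]`` is the PowerLawFit of module k (1-based) in group g;
    ``aic = -2 loglik + 2 * n_params``.
    """

    K: int
    labels: np.ndarray
    module_fits: dict
    aic: float
    loglik: float
    n_params: int
    converged: bool
    sigma2: np.ndarray | None = None
    mixing: np.ndarray | None = None


def _gene_features(series_by_group: np.ndarray, index: np.ndarray) -> np.ndarray:
    """Per-gene (slope, intercept) of log-log OLS, used to seed k-means."""
    lx = np.log(index)
    feats = []
    for y in series_by_group:
        y_adj = np.where(y > 0, y, np.nan)
        if np.isnan(y_adj).all():
            feats.append([0.0, 0.0])
            continue
        pos_min = np.nanmin(y_adj)
        ly = np.log(np.where(y > 0, y, 0.5 * pos_min))
        b, a = np.polyfit(lx, ly, 1)
        feats.append([b, a])
    return np.asarray(feats)


def functional_cluster(table: ExpressionTable, index: np.ndarray, K: int,
                       seed: int = 0, *, groups: dict | None = None,
                       max_iter: int = 200, tol: float = 1e-6,
                       n_restarts: int = 5) -> ModuleAssignment:
    """EM mixture of power curves over genes.

    Each module is a power curve per group evaluated on the ascending EI
    grid; residuals are independent Gaussians with a module-specific
    variance.  ``groups`` maps a group name to the column ids belonging to
    it (default: one group containing all columns).  Returns hard labels by
    maximum posterior; deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    m = table.shape[0]
    if K > m:
        raise ValueError("more modules than genes")
    index = np.asarray(index, dtype=float)
    if groups is None:
        groups = {"all": list(table.values.columns)}

    # serialize each group's columns by ascending index
    group_data = {}  # g -> (grid, genes x n matrix)
    col_pos = {c: i for i, c in enumerate(table.values.columns)}
    vals = table.values.to_numpy(dtype=float)
    for g, cols in groups.items():
        pos = [col_pos[c] for c in cols]
        idx_g = index[pos]
        order = np.argsort(idx_g, kind="stable")
        grid = idx_g[order]
        if np.any(grid <= 0):
            raise ValueError("index must be positive")
        group_data[g] = (grid, vals[:, pos][:, order])

    n_total = sum(gd[1].shape[1] for gd in group_data.values())
    G = len(group_data)
    n_params = K * 2 * G + K + (K - 1)

    rng = np.random.default_rng(seed)
    feats = np.concatenate([
        _gene_features(gd[1], gd[0]) for gd in group_data.values()
    ], axis=1)

    best = None
    for restart in range(n_restarts):
        labels0 = _kmeans_labels(feats, K, rng)
        result = _em_run(group_data, K, labels0, n_total, max_iter, tol)
        if best is None or result[1] > best[1]:
            best = result
    resp, loglik, fits, sigma2, mixing, converged = best

    labels = np.argmax(resp, axis=1) + 1
    module_fits = {k + 1: {g: fits[k][gi] for gi, g in enumerate(group_data)}
                   for k in range(K)}
    aic = -2.0 * loglik + 2.0 * n_params
    if not converged:
        logger.warning("EM did not converge in %d iterations (best iterate kept)", max_iter)
    return ModuleAssignment(K=K, labels=labels, module_fits=module_fits,
                            aic=float(aic), loglik=float(loglik),
                            n_params=n_params, converged=converged,
                            sigma2=sigma2, mixing=mixing)


def _kmeans_labels(feats: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    from sklearn.cluster import KMeans

    if K == 1:
        return np.zeros(feats.shape[0], dtype=int)
    km = KMeans(n_clusters=K, n_init=3,
                random_state=int(rng.integers(0, 2**31 - 1)))
    return km.fit_predict(feats)


def _em_run(group_data: dict, K: int, labels0: np.ndarray, n_total: int,
            max_iter: int, tol: float):
    m = next(iter(group_data.values()))[1].shape[0]
    resp = np.zeros((m, K))
    resp[np.arange(m), labels0] = 1.0
    mixing = resp.mean(axis=0)
    sigma2 = np.ones(K)
    fits = None
    prev_ll = -np.inf
    loglik = -np.inf
    converged = False

    for _ in range(max_iter):
        # M-step: weighted power fit per module per group; pooled variance
        fits = []
        sq = np.zeros((m, K))
        for k in range(K):
            w = resp[:, k]
            if w.sum() < 1e-10:
                w = np.full(m, 1e-10)
            k_fits = []
            for g, (grid, Y) in group_data.items():
                fit = _weighted_power_fit(grid, Y, w)
                k_fits.append(fit)
                sq[:, k] += np.sum((Y - fit.predict(grid)) ** 2, axis=1)
            fits.append(k_fits)
            sigma2[k] = max(np.sum(resp[:, k] * sq[:, k]) / (resp[:, k].sum() * n_total), 1e-12)
        mixing = np.clip(resp.mean(axis=0), 1e-12, None)
        mixing = mixing / mixing.sum()

        # E-step
        log_comp = (np.log(mixing)[None, :]
                    - 0.5 * n_total * np.log(2 * np.pi * sigma2)[None, :]
                    - 0.5 * sq / sigma2[None, :])
        mx = log_comp.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(log_comp - mx).sum(axis=1))
        resp = np.exp(log_comp - lse[:, None])
        loglik = float(lse.sum())
        if abs(loglik - prev_ll) < tol:
            converged = True
            break
        prev_ll = loglik
    return resp, loglik, fits, sigma2.copy(), mixing.copy(), converged


def _weighted_power_fit(grid: np.ndarray, Y: np.ndarray, w: np.ndarray) -> PowerLawFit:
    """Power fit minimizing sum_genes w_g * ||y_g - alpha x**beta||^2."""
    # pooled weighted series: replicate grid per gene with weights
    ybar = np.average(Y, axis=0, weights=w)  # weighted mean curve
    series = IndexedSeries(*_strict(grid, ybar))
    # fitting the weighted mean curve is equivalent for the LS power fit
    return fit_power_law(series)


def _strict(grid: np.ndarray, y: np.ndarray):
    from .data import _break_ties
    return _break_ties(grid), y


def select_module_count(table: ExpressionTable, index: np.ndarray,
                        K_range, seed: int = 0, *, groups: dict | None = None,
                        **kwargs) -> ModuleAssignment:
    """Run functional clustering over K_range and return the min-AIC fit."""
    K_list = list(K_range)
    if not K_list:
        raise ValueError("K_range is empty")
    best = None
    for K in K_list:
        fit = functional_cluster(table, index, K, seed=seed, groups=groups, **kwargs)
        logger.info("K=%d: loglik=%.3f AIC=%.3f", K, fit.loglik, fit.aic)
        if best is None or fit.aic < best.aic:
            best = fit
    return best
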