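"""Autocorrelated kernel density home-range estimation.

The kernel bandwidth uses the Gaussian reference rule with the
autocorrelation-adjusted (effective) sample size from the fitted movement
model, so strongly autocorrelated data smooth more than their nominal n
would suggest.  An optional debiasing step assigns per-observation weights
that minimise a quadratic mean-integrated-square-error criterion built
from the model's positional autocorrelation, down-weighting bursts of
temporally clustered (over-reported) observations.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import stats

from .types import LocationSeries, MovementModel, UtilisationDistribution

logger = logging.getLogger(__name__)

#: chi-square 95% quantile with 2 df; pi * this * sigma2 is the 95% Gaussian area.
CHI2_95_2D = float(stats.chi2.ppf(0.95, 2))


def bandwidth(model: MovementModel, series: LocationSeries) -> np.ndarray:
    """2x2 kernel covariance (m²): sigma2 * ess^(-1/3) * I.

    The 2-D Gaussian reference rule with the model's effective sample size
    in place of the nominal n.
    """
    ess = model.ess_area if np.isfinite(model.ess_area) else float(len(series))
    if model.family == "IID":
        ess = float(len(series))
    if ess <= 0:
        raise ValueError("non-positive effective sample size")
    h2 = model.sigma2 * ess ** (-1.0 / 3.0)
    return h2 * np.eye(2)


def _autocorr(model: MovementModel, lag: np.ndarray) -> np.ndarray:
    """Normalised positional autocorrelation rho(lag) of the fitted family."""
    lag = np.abs(np.asarray(lag, dtype=float))
    if model.family == "IID" or not model.tau_pos:
        return np.where(lag == 0, 1.0, 0.0)
    tp = model.tau_pos
    if model.family == "OU" or not model.tau_v:
        return np.exp(-lag / tp)
    tv = model.tau_v
    if abs(tp - tv) < 1e-10 * tp:
        return np.exp(-lag / tp) * (1.0 + lag / tp)
    return (tp * np.exp(-lag / tp) - tv * np.exp(-lag / tv)) / (tp - tv)


def _sampling_blocks(t: np.ndarray, gap: float = 90.0 * 86400.0):
    """Contiguous sampling blocks [(a, b), ...]; gaps > ``gap`` split blocks.

    Seasonal subsets of multi-year deployments consist of disjoint
    season-length blocks; the time-average estimand runs over those blocks
    only, not over the empty months between them.
    """
    cuts = np.flatnonzero(np.diff(t) > gap)
    starts = np.concatenate([[0], cuts + 1])
    ends = np.concatenate([cuts, [t.size - 1]])
    return [(t[a], t[b]) for a, b in zip(starts, ends)]


def _exp_block_integral(t: np.ndarray, a: float, b: float, tau: float) -> np.ndarray:
    """int_a^b exp(-|t - s| / tau) ds for each t (inside or outside [a, b])."""
    below = t < a
    above = t > b
    inside = ~(below | above)
    out = np.empty(t.size)
    out[below] = tau * (np.exp(-(a - t[below]) / tau) - np.exp(-(b - t[below]) / tau))
    out[above] = tau * (np.exp(-(t[above] - b) / tau) - np.exp(-(t[above] - a) / tau))
    out[inside] = tau * (2.0 - np.exp(-(t[inside] - a) / tau) - np.exp(-(b - t[inside]) / tau))
    return out


def _mean_autocorr_window(model: MovementModel, t: np.ndarray) -> np.ndarray:
    """k_i = (1/T) int_blocks rho(|t_i - s|) ds, in closed form.

    The linear MISE term: mean correlation of each observation with the
    range distribution time-averaged over the sampled blocks.
    """
    tp = model.tau_pos
    if model.family == "OUF" and model.tau_v and abs(tp - model.tau_v) > 1e-10 * tp:
        tv = model.tau_v
        comps = ((tp / (tp - tv), tp), (-tv / (tp - tv), tv))
    else:
        comps = ((1.0, tp),)
    blocks = _sampling_blocks(t)
    T = sum(b - a for a, b in blocks)
    T = max(T, 1e-9)
    out = np.zeros(t.size)
    for a, b in blocks:
        for c, tau in comps:
            out += c * _exp_block_integral(t, a, b, tau)
    return out / T


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / (np.arange(v.size) + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


def optimal_weights(
    series: LocationSeries,
    model: MovementModel,
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> np.ndarray:
    """Debiasing weights minimising w'Kw - 2k'w over the probability simplex.

    The quadratic MISE surrogate uses the fitted model's positional
    autocorrelation between observation times as the kernel-overlap matrix
    ``K_ij = rho(|t_i - t_j|)`` and, as the linear term, each observation's
    mean correlation with a uniform time grid over the tracking window
    (the time-averaged range distribution being the estimand).  Bursts of
    temporally clustered observations are strongly correlated and therefore
    share, and shrink, their total weight; for regular sampling the
    solution is uniform away from the window edges.  Solved by accelerated
    projected gradient from uniform weights; deterministic given inputs.
    """
    n = len(series)
    if n == 1:
        return np.ones(1)
    if model.family == "IID":
        return np.full(n, 1.0 / n)
    t = series.t
    K = _autocorr(model, t[None, :] - t[:, None])
    kvec = _mean_autocorr_window(model, t)
    # ridge-regularise if (numerically) singular, e.g. near-duplicate times
    w_eig = float(np.linalg.eigvalsh(K)[0])
    if w_eig < 1e-10:
        K = K + (1e-10 - min(w_eig, 0.0)) * np.eye(n)
        logger.warning("singular kernel-overlap matrix; ridge added")
    return _simplex_qp(K, kvec, tol=tol, max_iter=max_iter)


def _simplex_qp(K: np.ndarray, k: np.ndarray, tol: float = 1e-10,
                max_iter: int = 5000) -> np.ndarray:
    """min w'Kw - 2k'w s.t. w >= 0, sum w = 1, by a primal active set.

    Solves the equality-constrained problem on the current support via the
    KKT system, drops negative components, and re-admits zeroed components
    whose KKT multiplier is violated, until the duality gap (w'g - min g,
    g = 2(Kw - k)) falls below ``tol`` times the problem scale.  Falls back
    to projected gradient if the active set cycles.
    """
    n = k.size
    scale = float(np.abs(K).max())
    free = np.ones(n, dtype=bool)
    w = np.full(n, 1.0 / n)
    for _ in range(min(200, max_iter)):
        idx = np.flatnonzero(free)
        Ksub = K[np.ix_(idx, idx)]
        rhs = np.column_stack([k[idx], np.ones(idx.size)])
        try:
            sol = np.linalg.solve(Ksub, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(Ksub, rhs, rcond=None)
        a, b = sol[:, 0], sol[:, 1]
        denom = b.sum()
        lam = (1.0 - a.sum()) / denom if abs(denom) > 1e-300 else 0.0
        w_sub = a + lam * b
        if w_sub.min() < -1e-12:
            drop = idx[np.argmin(w_sub)]
            free[drop] = False
            if free.sum() == 0:  # pathological; bail to uniform
                return np.full(n, 1.0 / n)
            continue
        w = np.zeros(n)
        w[idx] = np.clip(w_sub, 0.0, None)
        w /= w.sum()
        g = 2.0 * (K @ w - k)
        gap = float(w @ g - g.min())
        if gap <= tol * max(scale, 1e-300):
            break
        # re-admit the zeroed component with the most violated multiplier
        zeroed = np.flatnonzero(~free)
        if zeroed.size == 0:
            break
        lam_hat = float(np.median(g[idx]))
        viol = lam_hat - g[zeroed]
        if viol.max() <= tol * max(scale, 1e-300):
            break
        free[zeroed[np.argmax(viol)]] = True
    return w


def akde(
    series: LocationSeries,
    model: MovementModel,
    debias: bool = False,
    cell: Optional[float] = None,
    padding: float = 4.0,
    max_cells_per_dim: int = 600,
    season: str = "annual",
) -> UtilisationDistribution:
    """Weighted Gaussian-kernel utilisation distribution on a regular grid.

    Grid defaults: cell size = bandwidth scale / 4, extent = observation
    bounding box padded by ``padding`` bandwidth scales; the grid expands
    automatically if it captures less than 99.99% of the kernel mass.
    """
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    H = bandwidth(model, series)
    h = float(np.sqrt(H[0, 0]))
    if cell is None:
        cell = h / 4.0
    w = optimal_weights(series, model) if debias else np.full(n, 1.0 / n)

    x, y = series.x, series.y
    pad = padding * h
    for _attempt in range(4):
        x_hi, y_hi = x.max() + pad, y.max() + pad
        x_lo, y_lo = x.min() - pad, y.min() - pad
        ncx = int(np.ceil((x_hi - x_lo) / cell))
        ncy = int(np.ceil((y_hi - y_lo) / cell))
        over = max(ncx, ncy) / max_cells_per_dim
        if over > 1.0:
            cell = cell * over
            ncx = int(np.ceil((x_hi - x_lo) / cell))
            ncy = int(np.ceil((y_hi - y_lo) / cell))
        # centre the (ceil-rounded) grid on the padded bounding box so the
        # overshoot is split evenly; symmetric data get a symmetric grid
        x_lo = 0.5 * (x_lo + x_hi) - 0.5 * ncx * cell
        y_lo = 0.5 * (y_lo + y_hi) - 0.5 * ncy * cell
        gx = x_lo + (np.arange(ncx) + 0.5) * cell
        gy = y_lo + (np.arange(ncy) + 0.5) * cell
        dens = np.zeros((ncy, ncx))
        inv2h2 = 1.0 / (2.0 * h * h)
        norm = 1.0 / (2.0 * np.pi * h * h)
        for i in range(n):
            ex = np.exp(-((gx - x[i]) ** 2) * inv2h2)
            ey = np.exp(-((gy - y[i]) ** 2) * inv2h2)
            dens += (w[i] * norm) * np.outer(ey[::-1], ex)
        mass = dens.sum() * cell * cell
        if mass >= 0.9999 or pad > 40.0 * h:
            break
        logger.warning("grid captured %.5f of mass; expanding", mass)
        pad *= 1.8
    dens /= dens.sum() * cell * cell
    return UtilisationDistribution(
        x0=x_lo,
        y0=y_lo,
        cell=cell,
        density=dens,
        dof_area=model.ess_area if model.family != "IID" else float(n),
        debiased=debias,
        season=season,
        individual_id=series.individual_id,
    )


def ud_area(ud: UtilisationDistribution, level: float = 0.95) -> float:
    """Area (km²) of the highest-density region holding ``level`` probability."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    p = np.nan_to_num(ud.density).ravel() * ud.cell_area
    order = np.argsort(p)[::-1]
    csum = np.cumsum(p[order])
    ncells = int(np.searchsorted(csum, level) + 1)
    return ncells * ud.cell_area / 1e6


def gaussian_area(model: MovementModel, level: float = 0.95,
                  include_periodic: bool = True) -> float:
    """95% area (km²) of the model's Gaussian-equivalent range.

    pi * chi2_quantile(level, 2 df) * total per-axis variance; with
    ``include_periodic`` the time-averaged variance of the seasonal mean
    loop is added to the stationary variance, so the area covers the full
    annual range rather than the instantaneous one.
    """
    var = model.sigma2
    if include_periodic and model.mean_coeffs is not None and model.n_harmonics > 0:
        c = np.asarray(model.mean_coeffs)
        var = var + float(np.mean((c[:, 1:] ** 2).sum(axis=1) / 2.0))
    q = float(stats.chi2.ppf(level, 2))
    return np.pi * q * var / 1e6
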