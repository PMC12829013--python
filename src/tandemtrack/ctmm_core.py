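"""Continuous-time movement models with periodic (seasonal) harmonic means.

The model family is IID (uncorrelated positions), OU (position
autocorrelation with range-crossing timescale tau_pos), and OUF (adds a
velocity autocorrelation timescale tau_v < tau_pos).  Each individual's
locations are modelled per axis as

    y(t) = m(t) + z(t) + measurement error,

where m(t) is a harmonic series of a fixed period (one year by default)
encoding seasonal migration, and z(t) is the stationary zero-mean Gaussian
process of the family with per-axis variance sigma2.  The exact Gaussian
likelihood is evaluated by a linear-Gaussian (Kalman) innovations filter
over the irregular observation grid; the harmonic mean is profiled out by
generalised least squares inside every likelihood evaluation.

Model selection follows a two-stage rule: AICc ranks the autocorrelation
families, and blocked cross-validated root-mean-square predictive error
(RMSPE) of the trend ranks the number of harmonics within the winning
family.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from ._kalman import whiten
from .types import LocationSeries, MovementModel, Semivariogram, SECONDS_PER_DAY, YEAR_SECONDS

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ------------------------------------------------------------ semivariance


def model_semivariance(model: MovementModel, lag) -> np.ndarray:
    """Closed-form per-axis semivariance of the family at the given lag(s).

    IID: gamma = sigma2 for lag > 0; OU: sigma2 (1 - exp(-lag/tau_pos));
    OUF: sigma2 [1 - (tau_pos e^{-lag/tau_pos} - tau_v e^{-lag/tau_v}) /
    (tau_pos - tau_v)], with the repeated-root limit at tau_pos = tau_v.
    """
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be non-negative")
    s2 = model.sigma2
    if model.family == "IID":
        return np.where(lag > 0, s2, 0.0)
    tp = model.tau_pos
    if model.family == "OU":
        return s2 * (1.0 - np.exp(-lag / tp))
    tv = model.tau_v
    if abs(tp - tv) < 1e-10 * tp:
        # repeated root: gamma = s2 [1 - e^{-l/t}(1 + l/t)]
        return s2 * (1.0 - np.exp(-lag / tp) * (1.0 + lag / tp))
    return s2 * (1.0 - (tp * np.exp(-lag / tp) - tv * np.exp(-lag / tv)) / (tp - tv))


def empirical_semivariogram(
    series: LocationSeries, bin_width: float = SECONDS_PER_DAY, max_lag: Optional[float] = None
) -> Semivariogram:
    """Per-axis empirical semivariance in lag bins of ``bin_width`` seconds.

    gamma(bin) = (1 / (4 N_bin)) sum ||r(t_j) - r(t_i)||^2 over pairs whose
    lag falls in the bin; the factor 4 = 2 (semivariance) x 2 (axes) makes
    the sill estimate the per-axis variance.
    """
    n = len(series)
    if n < 2:
        raise ValueError("need >= 2 observations")
    t, x, y = series.t, series.x, series.y
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be projected first")
    i, j = np.triu_indices(n, k=1)
    lag = t[j] - t[i]
    if max_lag is None:
        max_lag = series.duration / 2.0 if n > 50 else series.duration
    keep = lag <= max_lag
    i, j, lag = i[keep], j[keep], lag[keep]
    sq = (x[j] - x[i]) ** 2 + (y[j] - y[i]) ** 2
    bins = np.floor(lag / bin_width).astype(np.int64)
    nb = int(bins.max()) + 1 if bins.size else 0
    counts = np.bincount(bins, minlength=nb)
    sums = np.bincount(bins, weights=sq, minlength=nb)
    populated = counts > 0
    gamma = np.full(nb, np.nan)
    gamma[populated] = sums[populated] / (4.0 * counts[populated])
    centres = (np.arange(nb) + 0.5) * bin_width
    return Semivariogram(lag=centres[populated], gamma=gamma[populated],
                         counts=counts[populated], bin_width=bin_width)


def average_semivariograms(
    svs: Sequence[Semivariogram], labels: Optional[Sequence[str]] = None
) -> Dict[str, Semivariogram]:
    """Pair-count-weighted average per group (site x method, say)."""
    if labels is None:
        labels = ["all"] * len(svs)
    out: Dict[str, Semivariogram] = {}
    for group in sorted(set(labels)):
        members = [sv for sv, g in zip(svs, labels) if g == group]
        bw = members[0].bin_width
        if any(abs(m.bin_width - bw) > 1e-9 for m in members):
            raise ValueError("semivariograms must share a bin grid")
        nb = max(int(round(m.lag.max() / bw + 0.5)) for m in members)
        counts = np.zeros(nb)
        sums = np.zeros(nb)
        for m in members:
            idx = np.floor(m.lag / bw).astype(np.int64)
            counts[idx] += m.counts
            sums[idx] += m.counts * m.gamma
        pop = counts > 0
        centres = (np.arange(nb) + 0.5) * bw
        out[group] = Semivariogram(
            lag=centres[pop], gamma=sums[pop] / counts[pop], counts=counts[pop], bin_width=bw
        )
    return out


def range_residency_diagnostic(sv: Semivariogram, plateau_ratio: float = 0.8,
                               alpha: float = 0.05) -> Tuple[str, float]:
    """Automated plateau check standing in for visual variogram inspection.

    Resident iff the mean semivariance over the last quartile of lags is at
    least ``plateau_ratio`` of the global maximum AND the count-weighted
    slope over that quartile is statistically indistinguishable from zero.
    Returns (label, plateau score); label is "indeterminate" below 5 bins.
    """
    if sv.lag.size < 5:
        return "indeterminate", float("nan")
    qcut = np.quantile(sv.lag, 0.75)
    tail = sv.lag >= qcut
    score = float(np.mean(sv.gamma[tail]) / np.max(sv.gamma))
    lag_t, g_t, w_t = sv.lag[tail], sv.gamma[tail], sv.counts[tail].astype(float)
    if np.allclose(g_t, g_t[0]):
        slope_flat = True
    elif lag_t.size < 3:
        slope_flat = True
    else:
        W = np.diag(w_t / w_t.sum())
        X = np.column_stack([np.ones_like(lag_t), lag_t])
        XtW = X.T @ W
        beta, *_ = np.linalg.lstsq(XtW @ X, XtW @ g_t, rcond=None)
        resid = g_t - X @ beta
        dof = lag_t.size - 2
        s2 = (resid * (w_t / w_t.sum()) * resid).sum() * lag_t.size / max(dof, 1)
        cov = s2 * np.linalg.inv(XtW @ X)
        se = np.sqrt(max(cov[1, 1], 1e-300))
        tstat = beta[1] / se
        slope_flat = abs(tstat) < stats.t.ppf(1 - alpha / 2.0, max(dof, 1))
    label = "resident" if (score >= plateau_ratio and slope_flat) else "non-resident"
    return label, score


# ----------------------------------------------------------------- fitting


def harmonic_design(t: np.ndarray, period: float, n_harmonics: int) -> np.ndarray:
    """Design matrix [1, cos, sin, cos2, sin2, ...] for the periodic mean."""
    t = np.asarray(t, dtype=float)
    F = np.ones((t.size, 1 + 2 * n_harmonics))
    for h in range(1, n_harmonics + 1):
        ang = 2.0 * np.pi * h * t / period
        F[:, 2 * h - 1] = np.cos(ang)
        F[:, 2 * h] = np.sin(ang)
    return F


def aicc(loglik: float, k: int, n_eff: float) -> float:
    """Small-sample Akaike information criterion (nats)."""
    if n_eff <= k + 1:
        return float("inf")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_eff - k - 1)


def _profiled_loglik(family, dt, R, Y, F, sig2, tp, tv, reml=False):
    """Exact loglik with the harmonic mean profiled by GLS.

    Returns (loglik, beta (2, p), whitened residuals).  With ``reml`` the
    restricted likelihood is returned instead: the standard
    -0.5 log det(F' Sigma^-1 F) correction (per axis) removes the downward
    bias in variance/timescale estimates that plain ML incurs by fitting
    the mean from the same window.
    """
    n = Y.shape[0]
    M = np.hstack([Y, F])
    W, logdet = whiten(family, dt, R, M, sig2, tp, tv)
    Wy, Wf = W[:, :2], W[:, 2:]
    beta, *_ = np.linalg.lstsq(Wf, Wy, rcond=None)
    resid = Wy - Wf @ beta
    rss = (resid**2).sum(axis=0)
    ll = float(-0.5 * rss.sum() - logdet - n * _LOG2PI)
    if reml:
        sign, ld_f = np.linalg.slogdet(Wf.T @ Wf)
        if sign <= 0:
            return -np.inf, beta.T, resid
        ll -= ld_f  # once per axis, two axes sharing the design
    return ll, beta.T, resid


def _unpack(family: str, theta: np.ndarray, fit_error: bool):
    theta = np.clip(theta, -700.0, 700.0)  # keep exp finite for wild steps
    sig2 = np.exp(theta[0])
    tp = tv = 0.0
    k = 1
    if family in ("OU", "OUF"):
        tp = np.exp(theta[1])
        k = 2
        if family == "OUF":
            tv = tp / (1.0 + np.exp(-theta[2]))
            k = 3
    err = np.exp(theta[k]) if fit_error else None
    return sig2, tp, tv, err


def _neg_loglik(theta, family, dt, R0, Y, F, fit_error, reml=True):
    sig2, tp, tv, err = _unpack(family, theta, fit_error)
    if not np.isfinite(sig2) or sig2 <= 0:
        return 1e300
    R = R0 + err if err is not None else R0
    try:
        ll, _, _ = _profiled_loglik(family, dt, R, Y, F, sig2, tp, tv, reml=reml)
    except (np.linalg.LinAlgError, ValueError):
        return 1e300
    return -ll if np.isfinite(ll) else 1e300


def _variogram_init(series: LocationSeries, period: float, n_harmonics: int):
    """sigma2/tau starting values from detrended residual structure."""
    F = harmonic_design(series.t, period, n_harmonics)
    Y = np.column_stack([series.x, series.y])
    beta, *_ = np.linalg.lstsq(F, Y, rcond=None)
    resid = Y - F @ beta
    sig2 = float(resid.var(axis=0).mean())
    sig2 = max(sig2, 1e-6)
    # lag at which residual variogram reaches 1 - 1/e of sill
    try:
        rs = LocationSeries(series.individual_id, series.t, series.lon, series.lat,
                            x=resid[:, 0], y=resid[:, 1], error_radius=series.error_radius,
                            source=series.source)
        sv = empirical_semivariogram(rs)
        target = (1.0 - np.exp(-1.0)) * sig2
        hit = np.flatnonzero(sv.gamma >= target)
        tau0 = float(sv.lag[hit[0]]) if hit.size else series.duration / 5.0
    except ValueError:
        tau0 = series.duration / 5.0
    tau0 = min(max(tau0, 600.0), max(series.duration, 1200.0))
    return sig2, tau0


_FAMILY_NCOV = {"IID": 1, "OU": 2, "OUF": 3}


def fit_family(
    series: LocationSeries,
    family: str,
    n_harmonics: int = 0,
    period: float = YEAR_SECONDS,
    fit_error: Optional[bool] = None,
    multistart: Sequence[float] = (1.0, 0.3, 3.0),
    compute_cov: bool = True,
) -> Optional[MovementModel]:
    """Fit one family at a fixed harmonic count.

    Covariance parameters maximise the restricted (REML) likelihood — the
    harmonic mean is profiled by GLS inside every evaluation and the REML
    correction removes the finite-window bias in sigma2 and the timescales;
    the reported ``loglik``/``aicc`` are the plain likelihood at those
    parameters.  Measurement error handling: if the series carries per-fix
    error radii they enter the filter as known variances; otherwise an
    isotropic error variance is estimated alongside the process parameters
    (``fit_error`` overrides the automatic choice).  Returns None if no
    start converges.
    """
    n = len(series)
    p = 1 + 2 * n_harmonics
    if n < 2 or n <= p:
        return None
    t = series.t
    dt = np.diff(t)
    Y = np.column_stack([series.x, series.y])
    R0 = series.error_radius**2
    if fit_error is None:
        fit_error = bool(np.all(R0 == 0)) and family != "IID"
    F = harmonic_design(t, period, n_harmonics)

    sig0, tau0 = _variogram_init(series, period, n_harmonics)
    starts = []
    for mult in multistart:
        th = [np.log(sig0)]
        if family in ("OU", "OUF"):
            th.append(np.log(tau0 * mult))
            if family == "OUF":
                th.append(np.log(0.1 / 0.9))  # tau_v = tau_pos / 10
        if fit_error:
            th.append(np.log(max(sig0 * 1e-4, 1e-4)))
        starts.append(np.array(th))
        if family == "IID":
            break

    best = None
    args = (family, dt, R0, Y, F, fit_error)
    for th0 in starts:
        try:
            res = optimize.minimize(
                _neg_loglik, th0, args=args, method="L-BFGS-B",
                options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7},
            )
        except Exception:
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e299:
        logger.warning("fit failure: %s %s H=%d", series.individual_id, family, n_harmonics)
        return None

    theta = best.x
    sig2, tp, tv, err = _unpack(family, theta, fit_error)
    R = R0 + err if err is not None else R0
    ll, beta, _ = _profiled_loglik(family, dt, R, Y, F, sig2, tp, tv)
    k = _FAMILY_NCOV[family] + (1 if fit_error else 0) + 2 * p
    n_eff = 2.0 * n  # scalar observations: two axes per fix
    model = MovementModel(
        family=family,
        sigma2=sig2,
        tau_pos=tp if family != "IID" else None,
        tau_v=tv if family == "OUF" else None,
        period=period,
        n_harmonics=n_harmonics,
        mean_coeffs=beta,
        error_var=float(err) if err is not None else float(np.mean(R0)),
        loglik=ll,
        aicc=aicc(ll, k, n_eff),
        duration=series.duration,
        n_obs=n,
        individual_id=series.individual_id,
    )
    model.ess_area = effective_sample_size(model)
    if compute_cov:
        model.param_cov, model.param_names = _param_cov(theta, args)
    return model


def _param_cov(theta: np.ndarray, args) -> Tuple[Optional[np.ndarray], tuple]:
    """Observed-information covariance of the log-scale parameters."""
    family, _, _, _, _, fit_error = args
    names = ["log_sigma2"]
    if family in ("OU", "OUF"):
        names.append("log_tau_pos")
        if family == "OUF":
            names.append("w_tau_v")
    if fit_error:
        names.append("log_error_var")
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-4 * (1.0 + np.abs(theta))
    f0 = _neg_loglik(theta, *args)
    for a in range(k):
        for b in range(a, k):
            ta = theta.copy()
            ta[a] += h[a]
            ta[b] += h[b]
            tb = theta.copy()
            tb[a] += h[a]
            tb[b] -= h[b]
            tc = theta.copy()
            tc[a] -= h[a]
            tc[b] += h[b]
            td = theta.copy()
            td[a] -= h[a]
            td[b] -= h[b]
            H[a, b] = H[b, a] = (
                _neg_loglik(ta, *args)
                - _neg_loglik(tb, *args)
                - _neg_loglik(tc, *args)
                + _neg_loglik(td, *args)
            ) / (4.0 * h[a] * h[b])
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return None, tuple(names)
    return cov, tuple(names)


def tau_pos_interval(model: MovementModel, level: float = 0.95) -> Tuple[float, float]:
    """Wald interval for tau_pos from the log-scale observed information."""
    if model.tau_pos is None:
        raise ValueError("IID model has no tau_pos")
    if model.param_cov is None or "log_tau_pos" not in (model.param_names or ()):
        return (0.0, np.inf)
    i = model.param_names.index("log_tau_pos")
    se = float(np.sqrt(model.param_cov[i, i]))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (model.tau_pos * np.exp(-z * se), model.tau_pos * np.exp(z * se))


def effective_sample_size(model: MovementModel) -> float:
    """Independent observations implied by the model: n for IID, T/tau_pos else."""
    if model.family == "IID" or not model.tau_pos:
        return float(model.n_obs)
    if model.duration <= 0:
        return 0.0
    return float(model.duration / model.tau_pos)


def periodicity(model: MovementModel) -> float:
    """Percent of positional variance explained by the periodic mean.

    100 * V_m / (V_m + sigma2), where V_m is the time-averaged per-axis
    variance of the harmonic mean (sum of squared amplitudes / 2, averaged
    over axes); measurement error enters neither term.
    """
    if model.mean_coeffs is None or model.n_harmonics == 0:
        return 0.0
    c = np.asarray(model.mean_coeffs)
    amps = c[:, 1:]
    v_m = float(np.mean((amps**2).sum(axis=1) / 2.0))
    if v_m == 0.0:
        return 0.0
    return 100.0 * v_m / (v_m + model.sigma2)


def _blocked_folds(n: int, n_folds: int) -> List[np.ndarray]:
    edges = np.linspace(0, n, n_folds + 1).astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_folds) if edges[i + 1] > edges[i]]


def rmspe_cv(series: LocationSeries, model: MovementModel, n_folds: int = 10) -> float:
    """Blocked cross-validated RMSPE of the periodic trend (metres).

    Covariance parameters stay frozen at the full fit; for each contiguous
    held-out block the harmonic mean is re-estimated by GLS on the training
    blocks and the held-out locations are predicted from that trend.
    """
    n = len(series)
    n_folds = min(n_folds, n // 2)
    if n_folds < 2:
        return float("inf")
    t = series.t
    Y = np.column_stack([series.x, series.y])
    F = harmonic_design(t, model.period, model.n_harmonics)
    R_full = series.error_radius**2
    if np.all(R_full == 0):
        R_full = R_full + model.error_var
    sig2 = model.sigma2
    tp = model.tau_pos or 0.0
    tv = model.tau_v or 0.0
    sq_sum, count = 0.0, 0
    for fold in _blocked_folds(n, n_folds):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if mask.sum() <= F.shape[1]:
            continue
        dt_tr = np.diff(t[mask])
        M = np.hstack([Y[mask], F[mask]])
        W, _ = whiten(model.family, dt_tr, R_full[mask], M, sig2, tp, tv)
        beta, *_ = np.linalg.lstsq(W[:, 2:], W[:, :2], rcond=None)
        pred = F[fold] @ beta
        sq_sum += float(((Y[fold] - pred) ** 2).sum())
        count += fold.size
    if count == 0:
        return float("inf")
    return float(np.sqrt(sq_sum / (2 * count)))


def fit_ctmm(
    series: LocationSeries,
    period: float = YEAR_SECONDS,
    families: Sequence[str] = ("IID", "OU", "OUF"),
    harmonic_grid: Sequence[int] = (0, 1, 2, 3),
    fit_error: Optional[bool] = None,
    n_folds: int = 10,
) -> List[MovementModel]:
    """Fit and rank candidate movement models for one individual.

    Stage 1 fits every family at a reference harmonic count (the smallest
    positive entry of the grid, or 0) and ranks them by AICc; ties within
    1e-6 go to the model with fewer parameters.  Stage 2 refits the winning
    family at every harmonic count in the grid and ranks those by blocked
    cross-validated trend RMSPE.  The returned list has the selected model
    first, followed by the runners-up of stage 1.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 observations")
    grid = sorted(set(int(h) for h in harmonic_grid))
    h_ref = min([h for h in grid if h > 0], default=0)

    stage1: List[MovementModel] = []
    for fam in families:
        m = fit_family(series, fam, n_harmonics=h_ref, period=period, fit_error=fit_error)
        if m is not None:
            stage1.append(m)
    if not stage1:
        raise RuntimeError(f"all families failed for {series.individual_id}")
    stage1.sort(key=lambda m: (m.aicc, _FAMILY_NCOV[m.family]))
    # tie-break: within ~1e-6 AICc prefer fewer parameters
    best_aicc = stage1[0].aicc
    tied = [m for m in stage1 if m.aicc - best_aicc < 1e-6]
    tied.sort(key=lambda m: _FAMILY_NCOV[m.family])
    winner_family = tied[0].family

    candidates: List[MovementModel] = []
    for h in grid:
        m = (
            tied[0]
            if h == h_ref
            else fit_family(series, winner_family, n_harmonics=h, period=period, fit_error=fit_error)
        )
        if m is None:
            continue
        m.rmspe = rmspe_cv(series, m, n_folds=n_folds)
        if np.isfinite(m.rmspe):
            candidates.append(m)
    if not candidates:
        candidates = [tied[0]]
    candidates.sort(key=lambda m: (m.rmspe, m.n_harmonics))
    selected = candidates[0]
    runners = [m for m in stage1 if m.family != winner_family]
    return [selected] + runners
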