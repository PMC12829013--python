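"""Population-level (capture site x tracking method) meta-analysis.

Per-bird movement parameters and range areas are combined with a
random-effects hierarchical Gaussian model on a transformed scale
(log for timescales and areas, logit for bounded percentages):

    value_i ~ Normal(mu, s^2 + v_i),

where v_i is the bird's own sampling variance (from the fit's curvature)
and s^2 the between-bird variance, both estimated by maximum likelihood.
Intervals for the population mean come from the normal approximation to
mu-hat and are back-transformed.  The same machinery drives the
leave-out-k subsampling analysis of how many birds a site needs before
the mean range area stabilises.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .akde import gaussian_area
from .types import DevKSample, MetaEstimate, MovementModel, SECONDS_PER_DAY

logger = logging.getLogger(__name__)

_Z = {0.50: stats.norm.ppf(0.75), 0.75: stats.norm.ppf(0.875), 0.95: stats.norm.ppf(0.975)}


def select_contributors(
    models: Sequence[MovementModel],
    ess_min: float = 1.0,
    exclude_iid: bool = True,
) -> List[MovementModel]:
    """Filter fitted models for population averaging.

    Drops IID-selected birds (their selection flags unresolvable movement),
    non-finite estimates, and effective sample sizes below ``ess_min``
    (default 1; 10 in sensitivity mode).  Raises if a rule empties the set.
    """
    out = list(models)
    if not out:
        raise ValueError("no fitted models supplied")
    if exclude_iid:
        out = [m for m in out if m.family != "IID"]
        if not out:
            raise ValueError("IID exclusion removed every individual")
    out = [m for m in out if np.isfinite(m.sigma2) and (m.tau_pos is None or np.isfinite(m.tau_pos))]
    if not out:
        raise ValueError("finite-estimate rule removed every individual")
    out = [m for m in out if np.isfinite(m.ess_area) and m.ess_area >= ess_min]
    if not out:
        raise ValueError(f"effective-sample-size rule (>= {ess_min}) removed every individual")
    return out


def _transform(values: np.ndarray, scale: str) -> np.ndarray:
    if scale == "log":
        return np.log(values)
    if scale == "logit":
        v = np.clip(values, 1e-9, 1.0 - 1e-9)
        return np.log(v / (1.0 - v))
    return np.asarray(values, dtype=float)


def _back(x, scale: str):
    if scale == "log":
        return np.exp(x)
    if scale == "logit":
        return 1.0 / (1.0 + np.exp(-np.asarray(x)))
    return x


def meta_mean(
    values: Sequence[float],
    variances: Optional[Sequence[float]] = None,
    scale: str = "identity",
    parameter: str = "",
    group: str = "",
) -> MetaEstimate:
    """Random-effects population mean with 50/75/95% intervals.

    ``variances`` are per-contributor sampling variances on the transformed
    scale (zeros allowed).  With a single contributor the estimate is that
    value and the intervals reflect its sampling variance alone.
    """
    y = _transform(np.asarray(values, dtype=float), scale)
    v = np.zeros(y.size) if variances is None else np.asarray(variances, dtype=float)
    ok = np.isfinite(y) & np.isfinite(v)
    y, v = y[ok], v[ok]
    if y.size == 0:
        raise ValueError("no finite contributors")

    def profile_nll(log_s2: float) -> float:
        s2 = np.exp(log_s2)
        w = 1.0 / (s2 + v)
        mu = float(np.sum(w * y) / np.sum(w))
        return float(0.5 * np.sum(np.log(s2 + v) + w * (y - mu) ** 2))

    if y.size == 1:
        s2 = 0.0
    else:
        spread = max(float(np.var(y)), 1e-12)
        res = optimize.minimize_scalar(
            profile_nll, bounds=(np.log(spread) - 20.0, np.log(spread) + 6.0), method="bounded",
            options={"xatol": 1e-10},
        )
        s2 = float(np.exp(res.x))
        if profile_nll(np.log(max(spread * 1e-15, 1e-300))) < res.fun:
            s2 = 0.0  # degenerate to the fixed-effect weighted mean
    w = 1.0 / np.maximum(s2 + v, 1e-300)
    mu = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w))) if np.isfinite(np.sum(w)) else 0.0
    if y.size == 1 and v[0] == 0.0:
        se = 0.0

    def interval(level: float) -> Tuple[float, float]:
        z = _Z[level]
        return (float(_back(mu - z * se, scale)), float(_back(mu + z * se, scale)))

    return MetaEstimate(
        parameter=parameter,
        group=group,
        mean=float(_back(mu, scale)),
        ci50=interval(0.50),
        ci75=interval(0.75),
        ci95=interval(0.95),
        n_contributing=int(y.size),
    )


def _log_var(model: MovementModel, name: str) -> float:
    """Sampling variance of a log-scale parameter from the fit's curvature."""
    if model.param_cov is not None and model.param_names and name in model.param_names:
        i = model.param_names.index(name)
        var = float(model.param_cov[i, i])
        if np.isfinite(var) and var > 0:
            return var
    # chi-square fallback keyed to the effective degrees of freedom
    dof = max(model.ess_area, 1.0) if np.isfinite(model.ess_area) else 1.0
    return 2.0 / dof


def area_log_variance(model: MovementModel) -> float:
    """Delta-method variance of log(area): area scales with sigma2."""
    return _log_var(model, "log_sigma2")


def parameter_tables(
    models: Sequence[MovementModel],
    groups: Sequence[str],
    include_periodic_area: bool = True,
) -> List[MetaEstimate]:
    """Meta estimates of tau_pos (d), tau_v (d), periodicity (%), area (km²).

    Birds lacking a parameter (OU birds have no tau_v; stationary fits no
    periodicity) simply do not contribute to that parameter's mean, so the
    per-parameter n varies.
    """
    from .ctmm_core import periodicity as _periodicity

    out: List[MetaEstimate] = []
    for group in sorted(set(groups)):
        sub = [m for m, g in zip(models, groups) if g == group]
        tp = [(m.tau_pos / SECONDS_PER_DAY, _log_var(m, "log_tau_pos"))
              for m in sub if m.tau_pos]
        if tp:
            vals, var = zip(*tp)
            out.append(meta_mean(vals, var, scale="log", parameter="tau_pos_d", group=group))
        tv = [(m.tau_v / SECONDS_PER_DAY, _log_var(m, "w_tau_v")) for m in sub if m.tau_v]
        if tv:
            vals, var = zip(*tv)
            out.append(meta_mean(vals, var, scale="log", parameter="tau_v_d", group=group))
        per = [(_periodicity(m) / 100.0, 0.0) for m in sub if m.n_harmonics > 0]
        per = [(p, v) for p, v in per if 0.0 < p < 1.0]
        if per:
            vals, var = zip(*per)
            est = meta_mean(vals, var, scale="logit", parameter="periodicity_pct", group=group)
            out.append(
                MetaEstimate(
                    parameter="periodicity_pct",
                    group=group,
                    mean=est.mean * 100.0,
                    ci50=tuple(100.0 * c for c in est.ci50),
                    ci75=tuple(100.0 * c for c in est.ci75),
                    ci95=tuple(100.0 * c for c in est.ci95),
                    n_contributing=est.n_contributing,
                )
            )
        ar = [
            (gaussian_area(m, include_periodic=include_periodic_area), area_log_variance(m))
            for m in sub
        ]
        ar = [(a, v) for a, v in ar if np.isfinite(a) and a > 0]
        if ar:
            vals, var = zip(*ar)
            out.append(meta_mean(vals, var, scale="log", parameter="area_km2", group=group))
    return out


def _area_inputs(models: Sequence[MovementModel], include_periodic: bool):
    vals = np.array([gaussian_area(m, include_periodic=include_periodic) for m in models])
    var = np.array([area_log_variance(m) for m in models])
    return vals, var


def leave_out_k(
    models_by_group: Dict[str, Sequence[MovementModel]],
    n_replicates: int = 100,
    seed: int = 0,
    include_periodic_area: bool = True,
) -> List[DevKSample]:
    """Leave-out-k subsampling of the mean Gaussian range area.

    For every group with N >= 3 birds and every k in [2, N-1], draws
    ``n_replicates`` subsamples without replacement, recomputes the mean
    area with the same random-effects routine used globally, and records
    dev_k = (a_k - a_global) / a_global * 100 (percent).  Per-(group, k,
    replicate) random streams derive deterministically from ``seed``.
    """
    out: List[DevKSample] = []
    for gi, group in enumerate(sorted(models_by_group)):
        models = list(models_by_group[group])
        N = len(models)
        if N < 3:
            logger.info("group %s skipped in leave-out-k (N=%d < 3)", group, N)
            continue
        vals, var = _area_inputs(models, include_periodic_area)
        a_global = meta_mean(vals, var, scale="log").mean
        for k in range(2, N):
            for rep in range(n_replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(gi, k, rep))
                )
                idx = rng.choice(N, size=k, replace=False)
                a_k = meta_mean(vals[idx], var[idx], scale="log").mean
                out.append(
                    DevKSample(
                        group=group,
                        k=k,
                        replicate=rep + 1,
                        a_k=a_k,
                        dev_k=(a_k - a_global) / a_global * 100.0,
                    )
                )
    return out


def median_abs_deviation_by_k(devk: Sequence[DevKSample]) -> Dict[str, Dict[int, float]]:
    """Median over replicates of |dev_k|, per group and k."""
    out: Dict[str, Dict[int, float]] = {}
    for group in sorted({d.group for d in devk}):
        ks = sorted({d.k for d in devk if d.group == group})
        out[group] = {
            k: float(np.median([abs(d.dev_k) for d in devk if d.group == group and d.k == k]))
            for k in ks
        }
    return out


def min_sample_size(devk: Sequence[DevKSample], threshold: float = 10.0) -> Dict[str, Optional[int]]:
    """Smallest k per group with median |dev_k| below ``threshold`` percent."""
    med = median_abs_deviation_by_k(devk)
    out: Dict[str, Optional[int]] = {}
    for group, by_k in med.items():
        hit = [k for k in sorted(by_k) if by_k[k] < threshold]
        out[group] = hit[0] if hit else None
    return out
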