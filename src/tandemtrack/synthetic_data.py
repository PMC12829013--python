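"""Synthetic dual-channel tracking data.

Generates ground-truth goose-like trajectories — range-resident
Ornstein-Uhlenbeck-Foraging (OUF) motion about a one-year periodic mean
oscillating between a breeding and a wintering centroid — and observes each
trajectory through two channels:

* a GPS-like channel: near-daily scheduled fixes with independent dropout
  and small isotropic Gaussian position error, and
* a resight-like channel: an inhomogeneous Poisson process in time whose
  acceptance probability follows a spatially heterogeneous observer-effort
  surface (a mixture of Gaussian hotspots), producing the sparse, biased
  sighting records typical of coded-neckband reporting.

Mated pairs share one trajectory and differ only in observation noise.
Everything is bit-reproducible given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geo import ProjectionSpec
from .types import BirdMetadata, LocationSeries, SECONDS_PER_DAY, YEAR_SECONDS

#: 2018-01-01T00:00:00Z — epoch origin of all simulated clocks.
T0 = 1514764800.0
#: Day-of-year of the mid-June breeding-season anchor.
BREEDING_PEAK_DOY = 166.0


@dataclass(frozen=True)
class SiteTemplate:
    """Centroids and migratory make-up of one capture site."""

    name: str = "N"
    breeding_centroid: Tuple[float, float] = (0.0, 0.0)  # metres
    wintering_centroid: Tuple[float, float] = (0.0, -1.2e6)
    migratory_fraction: float = 1.0


@dataclass(frozen=True)
class EffortHotspot:
    """One Gaussian observer-effort hotspot."""

    x: float
    y: float
    weight: float
    scale: float  # metres


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic population.

    Defaults emulate the Swedish greylag regime: ~2-year deployments with
    daily GPS fixes retaining ~600 locations per bird, and opportunistic
    resighting at a rate yielding a median on the order of ten sightings
    per bird over the deployment.
    """

    seed: int = 0
    n_individuals: int = 20
    site_template: SiteTemplate = field(default_factory=SiteTemplate)
    tau_pos: float = 12.0 * SECONDS_PER_DAY
    tau_v: float = 0.3 * SECONDS_PER_DAY
    sigma2: float = (40e3) ** 2  # m², per axis (population median)
    sigma2_dispersion: float = 0.6  # lognormal sd of per-bird sigma2 factor
    migration_dispersion: float = 0.25  # lognormal sd of per-bird migration distance
    period: float = YEAR_SECONDS
    n_harmonics: int = 2
    migration_skew: float = 0.25  # 2nd-harmonic shape weight
    gps_interval: float = SECONDS_PER_DAY
    gps_failure_prob: float = 0.05
    gps_error_sd: float = 15.0  # metres
    resight_rate: float = 0.55  # median sightings per bird-month
    resight_rate_dispersion: float = 0.9  # lognormal sd of per-bird rate factor
    effort_surface: Sequence[EffortHotspot] = field(
        default_factory=lambda: (
            EffortHotspot(0.0, 0.0, 1.0, 2.5e5),
            EffortHotspot(0.0, -1.2e6, 1.5, 2.0e5),
        )
    )
    duration: float = 630.0 * SECONDS_PER_DAY
    pair_fraction: float = 0.2
    gps_fraction: float = 0.5
    frame: ProjectionSpec = field(default_factory=lambda: ProjectionSpec(15.0, 55.0))

    def __post_init__(self):
        if not (0 < self.tau_v < self.tau_pos):
            raise ValueError("requires 0 < tau_v < tau_pos")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        for p in (self.gps_failure_prob, self.pair_fraction, self.gps_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(h.weight < 0 for h in self.effort_surface):
            raise ValueError("effort weights must be non-negative")


@dataclass
class Trajectory:
    """Dense ground-truth path with the generating parameters."""

    individual_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    params: dict


def harmonic_coefficients(template: SiteTemplate, n_harmonics: int,
                          period: float = YEAR_SECONDS,
                          skew: float = 0.25) -> np.ndarray:
    """Fourier coefficients of the seasonal mean loop, shape (2, 1+2H).

    The loop interpolates between the breeding centroid (mid-June) and the
    wintering centroid (mid-December).  With two or more harmonics a shape
    term ``skew * (cos 2θ - 1)`` skews residence times while leaving both
    anchor points fixed.  Coefficients are ordered
    ``[intercept, a_1, b_1, a_2, b_2, ...]`` per axis.
    """
    b = np.asarray(template.breeding_centroid, dtype=float)
    w = np.asarray(template.wintering_centroid, dtype=float)
    mid, amp = (b + w) / 2.0, (b - w) / 2.0
    theta0 = 2.0 * np.pi * (BREEDING_PEAK_DOY * SECONDS_PER_DAY) / period
    coeffs = np.zeros((2, 1 + 2 * max(n_harmonics, 0)))
    if n_harmonics == 0:
        coeffs[:, 0] = b
        return coeffs
    coeffs[:, 0] = mid
    # cos(θ - θ0) = cosθ0·cosθ + sinθ0·sinθ, θ = 2π t / period
    coeffs[:, 1] = amp * np.cos(theta0)
    coeffs[:, 2] = amp * np.sin(theta0)
    if n_harmonics >= 2 and skew != 0.0:
        coeffs[:, 0] -= skew * amp
        coeffs[:, 3] = skew * amp * np.cos(2.0 * theta0)
        coeffs[:, 4] = skew * amp * np.sin(2.0 * theta0)
    return coeffs


def periodic_mean(t, template: SiteTemplate, n_harmonics: int,
                  period: float = YEAR_SECONDS, skew: float = 0.25) -> np.ndarray:
    """Seasonal mean location at times ``t`` (seconds); shape (len(t), 2)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    coeffs = harmonic_coefficients(template, n_harmonics, period, skew)
    H = (coeffs.shape[1] - 1) // 2
    F = np.ones((t.size, 1 + 2 * H))
    for h in range(1, H + 1):
        ang = 2.0 * np.pi * h * t / period
        F[:, 2 * h - 1] = np.cos(ang)
        F[:, 2 * h] = np.sin(ang)
    return F @ coeffs.T


def _ouf_transition(dt: float, tau_pos: float, tau_v: float, sigma2: float):
    """Exact linear-Gaussian transition (Phi, Q) of the OUF state (z, v)."""
    r1, r2 = 1.0 / tau_pos, 1.0 / tau_v
    if abs(r2 - r1) < 1e-10 * r2:
        r = 0.5 * (r1 + r2)
        e = np.exp(-r * dt)
        Phi = e * np.array([[1.0 + r * dt, dt], [-r * r * dt, 1.0 - r * dt]])
    else:
        e1, e2 = np.exp(-r1 * dt), np.exp(-r2 * dt)
        d = r2 - r1
        Phi = np.array(
            [
                [(r2 * e1 - r1 * e2) / d, (e1 - e2) / d],
                [r1 * r2 * (e2 - e1) / d, (r2 * e2 - r1 * e1) / d],
            ]
        )
    Pinf = np.diag([sigma2, sigma2 * r1 * r2])
    Q = Pinf - Phi @ Pinf @ Phi.T
    # symmetrise and guard tiny negative eigenvalues from cancellation
    Q = 0.5 * (Q + Q.T)
    return Phi, Q


def _chol_psd(Q: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(Q)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(Q)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_trajectory(config: SimulationConfig, individual_id: str,
                        rng: Optional[np.random.Generator] = None,
                        migratory: Optional[bool] = None,
                        sigma2: Optional[float] = None,
                        template: Optional[SiteTemplate] = None) -> Trajectory:
    """Exact discrete-time simulation of the OUF deviation about the seasonal mean.

    The (position, velocity) state is propagated with its exact
    linear-Gaussian transition at an internal step of ``min(tau_v/5, 6 h)``,
    so there is no time-discretisation error; the stationary per-axis
    variance of the deviation is ``config.sigma2``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tpl = config.site_template if template is None else template
    if migratory is None:
        migratory = bool(rng.random() < tpl.migratory_fraction)
    n_h = config.n_harmonics if migratory else 0
    sig2 = config.sigma2 if sigma2 is None else float(sigma2)

    dt = min(config.tau_v / 5.0, 6 * 3600.0)
    n_steps = int(np.ceil(config.duration / dt)) + 1
    t = T0 + dt * np.arange(n_steps)
    Phi, Q = _ouf_transition(dt, config.tau_pos, config.tau_v, sig2)
    L = _chol_psd(Q)
    Pinf_L = _chol_psd(np.diag([sig2, sig2 / (config.tau_pos * config.tau_v)]))

    # state: rows (z, v), columns (x-axis, y-axis); start at stationarity
    state = Pinf_L @ rng.standard_normal((2, 2))
    dev = np.empty((n_steps, 2))
    dev[0] = state[0]
    noise = rng.standard_normal((n_steps - 1, 2, 2))
    for i in range(1, n_steps):
        state = Phi @ state + L @ noise[i - 1]
        dev[i] = state[0]

    mean = periodic_mean(t - T0, tpl, n_h, config.period, config.migration_skew)
    path = mean + dev
    return Trajectory(
        individual_id=individual_id,
        t=t,
        x=path[:, 0],
        y=path[:, 1],
        params={
            "tau_pos": config.tau_pos,
            "tau_v": config.tau_v,
            "sigma2": sig2,
            "n_harmonics": n_h,
            "migratory": migratory,
            "period": config.period,
        },
    )


def _path_at(traj: Trajectory, t: np.ndarray) -> np.ndarray:
    x = np.interp(t, traj.t, traj.x)
    y = np.interp(t, traj.t, traj.y)
    return np.column_stack([x, y])


def _to_series(individual_id: str, t: np.ndarray, xy: np.ndarray,
               err: float, source: str, frame: ProjectionSpec) -> LocationSeries:
    lon, lat = frame.inverse(xy[:, 0], xy[:, 1])
    return LocationSeries(
        individual_id=individual_id,
        t=t,
        lon=np.atleast_1d(lon),
        lat=np.atleast_1d(lat),
        x=xy[:, 0],
        y=xy[:, 1],
        error_radius=np.full(t.size, err),
        source=source,
    )


def observe_gps(traj: Trajectory, config: SimulationConfig,
                rng: Optional[np.random.Generator] = None) -> LocationSeries:
    """Scheduled fixes with independent dropout and isotropic Gaussian error."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_fix = int(np.floor((traj.t[-1] - traj.t[0]) / config.gps_interval + 1e-9)) + 1
    t_sched = traj.t[0] + config.gps_interval * np.arange(n_fix)
    keep = rng.random(t_sched.size) >= config.gps_failure_prob
    t_obs = t_sched[keep]
    xy = _path_at(traj, t_obs)
    if config.gps_error_sd > 0:
        xy = xy + rng.normal(0.0, config.gps_error_sd, xy.shape)
    return _to_series(traj.individual_id, t_obs, xy, config.gps_error_sd, "gps", config.frame)


def effort_at(xy: np.ndarray, surface: Sequence[EffortHotspot]) -> np.ndarray:
    """Observer-effort intensity (arbitrary units) at planar positions."""
    xy = np.atleast_2d(xy)
    out = np.zeros(xy.shape[0])
    for h in surface:
        d2 = (xy[:, 0] - h.x) ** 2 + (xy[:, 1] - h.y) ** 2
        out += h.weight * np.exp(-0.5 * d2 / h.scale**2)
    return out


def observe_cmr(traj: Trajectory, config: SimulationConfig,
                rng: Optional[np.random.Generator] = None) -> LocationSeries:
    """Opportunistic sightings: effort-thinned inhomogeneous Poisson process.

    A dominating homogeneous Poisson process is thinned by the acceptance
    probability ``effort(r_t) / max effort``; the dominating rate is scaled
    so the expected accepted count matches the bird's reporting rate given
    its actual use of the effort surface.  Reporting rates are strongly
    heterogeneous across birds (some birds frequent well-watched parks,
    others are never seen): each bird draws a lognormal rate factor with
    log-sd ``resight_rate_dispersion`` around the median ``resight_rate``
    sightings per bird-month.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    surface = list(config.effort_surface)
    if not surface or all(h.weight == 0 for h in surface):
        raise ValueError("effort surface is empty or all-zero")
    T = traj.t[-1] - traj.t[0]
    factor = float(np.exp(rng.normal(0.0, config.resight_rate_dispersion)))
    rate_s = config.resight_rate * factor / (30.4375 * SECONDS_PER_DAY)
    if rate_s <= 0:
        return _to_series(traj.individual_id, np.empty(0), np.empty((0, 2)), 0.0, "resight", config.frame)

    path_eff = effort_at(np.column_stack([traj.x, traj.y]), surface)
    eff_max = float(path_eff.max())
    mean_acc = float(path_eff.mean()) / eff_max if eff_max > 0 else 0.0
    if mean_acc <= 0:
        return _to_series(traj.individual_id, np.empty(0), np.empty((0, 2)), 0.0, "resight", config.frame)
    lam_dom = rate_s / mean_acc

    n_dom = rng.poisson(lam_dom * T)
    t_cand = np.sort(traj.t[0] + rng.random(n_dom) * T)
    xy = _path_at(traj, t_cand)
    acc = effort_at(xy, surface) / eff_max
    keep = rng.random(n_dom) < acc
    # resight coordinates are the reported bird position (observer rounding
    # etc. treated as ~100 m error)
    err = 100.0
    xy_obs = xy[keep] + rng.normal(0.0, err, (int(keep.sum()), 2))
    return _to_series(traj.individual_id, t_cand[keep], xy_obs, err, "resight", config.frame)


def make_population(config: SimulationConfig):
    """Simulate the full population: (metadata, series list, truth table).

    A ``pair_fraction`` of birds is generated as mated pairs sharing one
    trajectory with independent observation noise; each bird is assigned
    the GPS or the neckband channel.  Returns per-bird
    :class:`BirdMetadata`, one observed :class:`LocationSeries` per bird,
    and a truth table (``pandas.DataFrame``) of generating parameters.
    """
    ss = np.random.SeedSequence(config.seed)
    n = config.n_individuals
    n_pairs = int(round(config.pair_fraction * n / 2.0))
    n_traj = n - n_pairs
    child = ss.spawn(n_traj + 2)
    rng_assign = np.random.default_rng(child[-1])

    n_gps = int(round(config.gps_fraction * n))
    methods = np.array(["gps"] * n_gps + ["neckband"] * (n - n_gps))
    rng_assign.shuffle(methods)

    meta: List[BirdMetadata] = []
    series: List[LocationSeries] = []
    truth_rows = []
    bird_idx = 0
    site = config.site_template.name
    for j in range(n_traj):
        rng = np.random.default_rng(child[j])
        paired = j < n_pairs
        members = 2 if paired else 1
        ids = [f"{site}{bird_idx + m:03d}" for m in range(members)]
        # individual range sizes and migration distances vary strongly in
        # the wild (short-stopping): lognormal per-trajectory factors
        sig2_j = config.sigma2 * float(np.exp(rng.normal(0.0, config.sigma2_dispersion)))
        mig_j = float(np.exp(rng.normal(0.0, config.migration_dispersion)))
        tpl = config.site_template
        b = np.asarray(tpl.breeding_centroid)
        w = b + mig_j * (np.asarray(tpl.wintering_centroid) - b)
        tpl_j = SiteTemplate(tpl.name, tuple(b), tuple(w), tpl.migratory_fraction)
        traj = simulate_trajectory(config, ids[0], rng=rng, sigma2=sig2_j, template=tpl_j)
        for m, bid in enumerate(ids):
            traj_m = Trajectory(bid, traj.t, traj.x, traj.y, traj.params)
            method = methods[bird_idx]
            obs = (
                observe_gps(traj_m, config, rng=rng)
                if method == "gps"
                else observe_cmr(traj_m, config, rng=rng)
            )
            partner = ids[1 - m] if paired else None
            meta.append(
                BirdMetadata(
                    individual_id=bid,
                    capture_site=site,
                    capture_date="2018-06-15",
                    sex="f" if rng.random() < 0.5 else "m",
                    age_at_capture="adult",
                    method=method,
                    pair_partner_id=partner,
                )
            )
            series.append(obs)
            truth_rows.append(
                {
                    "individual_id": bid,
                    "capture_site": site,
                    "method": method,
                    "pair_partner_id": partner or "",
                    "trajectory_id": ids[0],
                    "n_obs": len(obs),
                    **traj.params,
                }
            )
            bird_idx += 1
    truth = pd.DataFrame(truth_rows)
    return meta, series, truth
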