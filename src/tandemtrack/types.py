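"""Shared domain containers for the dual-channel tracking pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

SECONDS_PER_DAY = 86400.0
YEAR_SECONDS = 365.25 * SECONDS_PER_DAY


@dataclass(frozen=True)
class BirdMetadata:
    """Per-bird deployment record (capture context and marking method)."""

    individual_id: str
    capture_site: str
    capture_date: str  # ISO calendar date
    sex: str = "u"  # {m, f, u}
    age_at_capture: str = "adult"  # {juvenile, adult}
    method: str = "gps"  # {gps, neckband}
    pair_partner_id: Optional[str] = None


@dataclass
class LocationSeries:
    """One individual's time-ordered observations.

    Attributes
    ----------
    t : array of float
        UTC timestamps in seconds; strictly increasing.
    lon, lat : arrays of float, degrees WGS84.
    x, y : arrays of float, metres in the working projection (NaN until
        :func:`tandemtrack.io_model.project` is applied).
    error_radius : array of float
        1-sigma circular location error, metres.
    source : {"gps", "resight"}
    satellites : optional array of int
        GPS satellite count per fix, where known.
    """

    individual_id: str
    t: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    x: np.ndarray = None  # type: ignore[assignment]
    y: np.ndarray = None  # type: ignore[assignment]
    error_radius: np.ndarray = None  # type: ignore[assignment]
    source: str = "gps"
    satellites: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = self.t.size
        if self.x is None:
            self.x = np.full(n, np.nan)
        if self.y is None:
            self.y = np.full(n, np.nan)
        if self.error_radius is None:
            self.error_radius = np.zeros(n)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.error_radius = np.asarray(self.error_radius, dtype=float)
        if self.satellites is not None:
            self.satellites = np.asarray(self.satellites)
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
        if np.any(self.error_radius < 0):
            raise ValueError("negative error radius")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        """Span of the series in seconds (0 for < 2 observations)."""
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def take(self, idx) -> "LocationSeries":
        """Sub-series at integer/boolean index ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return LocationSeries(
            individual_id=self.individual_id,
            t=self.t[idx],
            lon=self.lon[idx],
            lat=self.lat[idx],
            x=self.x[idx],
            y=self.y[idx],
            error_radius=self.error_radius[idx],
            source=self.source,
            satellites=None if self.satellites is None else self.satellites[idx],
        )


@dataclass
class Semivariogram:
    """Empirical semivariance per lag bin (default bin width 24 h)."""

    lag: np.ndarray  # bin centres, seconds
    gamma: np.ndarray  # m^2 per axis
    counts: np.ndarray  # pairs per bin
    bin_width: float = SECONDS_PER_DAY


@dataclass
class MovementModel:
    """Fitted continuous-time movement model with a periodic harmonic mean.

    ``family`` is one of IID (no autocorrelation), OU (position
    autocorrelation timescale ``tau_pos``), or OUF (adds the velocity
    timescale ``tau_v``).  ``sigma2`` is the per-axis stationary variance of
    the stochastic component; ``mean_coeffs`` holds, per axis, the intercept
    followed by (cos, sin) amplitudes for each harmonic of ``period``.
    """

    family: str
    sigma2: float
    tau_pos: Optional[float] = None
    tau_v: Optional[float] = None
    period: float = YEAR_SECONDS
    n_harmonics: int = 0
    mean_coeffs: Optional[np.ndarray] = None  # shape (2, 1 + 2*n_harmonics)
    error_var: float = 0.0
    loglik: float = np.nan
    aicc: float = np.nan
    rmspe: float = np.nan
    ess_area: float = np.nan
    duration: float = 0.0
    n_obs: int = 0
    individual_id: str = ""
    param_cov: Optional[np.ndarray] = None  # cov of log-scale cov params
    param_names: Optional[tuple] = None

    def mean_at(self, t) -> np.ndarray:
        """Periodic mean location at times ``t``; shape (len(t), 2), metres."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        from .ctmm_core import harmonic_design  # local import to avoid cycle

        F = harmonic_design(t, self.period, self.n_harmonics)
        if self.mean_coeffs is None:
            return np.zeros((t.size, 2))
        return F @ np.asarray(self.mean_coeffs).T


@dataclass
class UtilisationDistribution:
    """Normalised space-use density on a regular planar grid."""

    x0: float  # x of lower-left cell corner, metres
    y0: float
    cell: float  # cell size, metres
    density: np.ndarray  # (nrows, ncols), row 0 = northernmost; m^-2
    dof_area: float = np.nan
    debiased: bool = False
    season: str = "annual"
    individual_id: str = ""

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def total_mass(self) -> float:
        return float(np.nansum(self.density) * self.cell_area)


@dataclass(frozen=True)
class OverlapRecord:
    """A pairwise Bhattacharyya overlap with its comparison class."""

    id_a: str
    id_b: str
    comparison_class: str  # GPS-GPS | NB-NB | GPS-NB | self-debias
    capture_site: str
    season: str
    bc: float
    ess: float


@dataclass(frozen=True)
class MetaEstimate:
    """Population (site x method) mean with nested confidence intervals."""

    parameter: str
    group: str
    mean: float
    ci50: tuple
    ci75: tuple
    ci95: tuple
    n_contributing: int


@dataclass(frozen=True)
class DevKSample:
    """One leave-out-k replicate: subsample mean area and % deviation."""

    group: str
    k: int
    replicate: int
    a_k: float
    dev_k: float
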