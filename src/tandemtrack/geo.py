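"""Geodesy for telemetry analysis: equal-area projection and geodesic distance.

All analyses run in a single planar frame so that variances are in m² and
areas in km² without further bookkeeping.  The frame is an oblique Lambert
azimuthal equal-area projection evaluated on the authalic sphere of the
WGS84 ellipsoid: latitudes are converted to authalic latitudes first, which
makes the projection area-preserving with respect to the ellipsoid to well
below 0.5%.  Point-to-point distances on the ellipsoid use Vincenty's
inverse method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_B = _A * (1.0 - _F)
_E2 = _F * (2.0 - _F)
_E = np.sqrt(_E2)


def _authalic_q(phi: np.ndarray) -> np.ndarray:
    s = np.sin(phi)
    return (1.0 - _E2) * (
        s / (1.0 - _E2 * s * s)
        - (1.0 / (2.0 * _E)) * np.log((1.0 - _E * s) / (1.0 + _E * s))
    )


_QP = float(_authalic_q(np.asarray(np.pi / 2)))
#: Radius of the sphere with the same surface area as the WGS84 ellipsoid.
AUTHALIC_RADIUS = _A * np.sqrt(_QP / 2.0)


def _authalic_latitude(phi: np.ndarray) -> np.ndarray:
    return np.arcsin(np.clip(_authalic_q(phi) / _QP, -1.0, 1.0))


def _inverse_authalic_latitude(beta: np.ndarray) -> np.ndarray:
    # Newton iteration on q(phi) = q_p * sin(beta); converges in ~3 steps.
    phi = np.asarray(beta, dtype=float).copy()
    target = _QP * np.sin(beta)
    for _ in range(6):
        s = np.sin(phi)
        q = _authalic_q(phi)
        dq_dphi = (
            (1.0 - _E2)
            * np.cos(phi)
            * ((1.0 + _E2 * s * s) / (1.0 - _E2 * s * s) ** 2 + 1.0 / (1.0 - _E2 * s * s))
        )
        # guard the poles where dq/dphi -> 0
        dq_dphi = np.where(np.abs(dq_dphi) < 1e-12, 1e-12, dq_dphi)
        phi = phi - (q - target) / dq_dphi
        phi = np.clip(phi, -np.pi / 2, np.pi / 2)
    return phi


@dataclass(frozen=True)
class ProjectionSpec:
    """Oblique Lambert azimuthal equal-area frame about a reference point.

    Parameters
    ----------
    reference_lon, reference_lat
        Projection centre in degrees (WGS84).
    """

    reference_lon: float
    reference_lat: float

    def forward(self, lon, lat):
        """Project lon/lat (degrees) to planar x/y metres.

        Raises
        ------
        ValueError
            If any point is antipodal to the projection centre, where the
            projection is singular.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lam = np.radians(lon)
        lam0 = np.radians(self.reference_lon)
        beta = _authalic_latitude(np.radians(lat))
        beta0 = float(_authalic_latitude(np.asarray(np.radians(self.reference_lat))))
        R = AUTHALIC_RADIUS

        cosc = np.sin(beta0) * np.sin(beta) + np.cos(beta0) * np.cos(beta) * np.cos(lam - lam0)
        if np.any(cosc <= -1.0 + 1e-12):
            raise ValueError("point antipodal to projection centre")
        kprime = np.sqrt(2.0 / (1.0 + cosc))
        x = R * kprime * np.cos(beta) * np.sin(lam - lam0)
        y = R * kprime * (
            np.cos(beta0) * np.sin(beta) - np.sin(beta0) * np.cos(beta) * np.cos(lam - lam0)
        )
        return x, y

    def inverse(self, x, y):
        """Planar x/y metres back to lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        R = AUTHALIC_RADIUS
        lam0 = np.radians(self.reference_lon)
        beta0 = float(_authalic_latitude(np.asarray(np.radians(self.reference_lat))))
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / (2.0 * R), -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(
                rho > 0,
                np.arcsin(
                    np.clip(
                        np.cos(c) * np.sin(beta0) + y * np.sin(c) * np.cos(beta0) / np.where(rho > 0, rho, 1.0),
                        -1.0,
                        1.0,
                    )
                ),
                beta0,
            )
            lam = lam0 + np.arctan2(
                x * np.sin(c),
                rho * np.cos(beta0) * np.cos(c) - y * np.sin(beta0) * np.sin(c),
            )
        lam = np.where(rho > 0, lam, lam0)
        lat = np.degrees(_inverse_authalic_latitude(beta))
        lon = np.degrees(lam)
        lon = (lon + 180.0) % 360.0 - 180.0
        return lon, lat


def geodesic_distance(lon1, lat1, lon2, lat2, tol: float = 1e-12, maxiter: int = 200):
    """WGS84 geodesic distance in metres (Vincenty inverse method).

    Accepts scalars or broadcastable arrays.  Falls back to the spherical
    great-circle distance on the authalic sphere for the rare near-antipodal
    pairs where Vincenty's iteration fails to converge.
    """
    lon1, lat1, lon2, lat2 = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (lon1, lat1, lon2, lat2))
    )
    U1 = np.arctan((1 - _F) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1 - _F) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    converged = np.zeros(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)

    for _ in range(maxiter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sin_lam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * cos_lam) ** 2
        )
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sin_alpha = np.where(sin_sigma > 0, cosU1 * cosU2 * sin_lam / np.where(sin_sigma > 0, sin_sigma, 1.0), 0.0)
        cos_sq_alpha = 1.0 - sin_alpha**2
        with np.errstate(invalid="ignore", divide="ignore"):
            cos2sm = np.where(
                cos_sq_alpha > 0,
                cos_sigma - 2.0 * sinU1 * sinU2 / np.where(cos_sq_alpha > 0, cos_sq_alpha, 1.0),
                0.0,
            )
        C = _F / 16.0 * cos_sq_alpha * (4.0 + _F * (4.0 - 3.0 * cos_sq_alpha))
        lam_new = L + (1.0 - C) * _F * sin_alpha * (
            sigma + C * sin_sigma * (cos2sm + C * cos_sigma * (-1.0 + 2.0 * cos2sm**2))
        )
        converged = np.abs(lam_new - lam) < tol
        lam = lam_new
        if np.all(converged):
            break

    u_sq = cos_sq_alpha * (_A**2 - _B**2) / _B**2
    big_a = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    big_b = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = big_b * sin_sigma * (
        cos2sm
        + big_b / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - big_b / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    dist = _B * big_a * (sigma - delta_sigma)

    if not np.all(converged):  # near-antipodal fallback
        hav = _great_circle(lon1, lat1, lon2, lat2)
        dist = np.where(converged, dist, hav)
    if dist.ndim == 0:
        return float(dist)
    return dist


def _great_circle(lon1, lat1, lon2, lat2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    h = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2.0 * AUTHALIC_RADIUS * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
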