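"""Innovations (Kalman) filters for the IID/OU/OUF observation covariance.

Each filter runs the state-space recursion over an irregular time grid and
returns the *whitened* version of every input column (data columns and
periodic-mean design columns alike) together with the log-determinant of
the observation covariance.  Because whitening is a linear operator that
depends only on the covariance parameters, generalised least squares for
the harmonic mean reduces to ordinary least squares on the whitened
columns, and the exact Gaussian likelihood follows from the whitened
residuals plus the log-determinant.

The recursions are jit-compiled with numba when available; a pure-Python
fallback with identical semantics is used otherwise.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _whiten_iid(R, M, sig2):
    n, m = M.shape
    W = np.empty((n, m))
    logdet = 0.0
    for i in range(n):
        S = sig2 + R[i]
        logdet += math.log(S)
        rs = 1.0 / math.sqrt(S)
        for j in range(m):
            W[i, j] = M[i, j] * rs
    return W, logdet


@njit(cache=False)
def _whiten_ou(dt, R, M, sig2, tau):
    n, m = M.shape
    W = np.empty((n, m))
    a = np.zeros(m)
    P = sig2
    logdet = 0.0
    for i in range(n):
        if i > 0:
            phi = math.exp(-dt[i - 1] / tau)
            P = phi * phi * P + sig2 * (1.0 - phi * phi)
            for j in range(m):
                a[j] *= phi
        S = P + R[i]
        logdet += math.log(S)
        rs = 1.0 / math.sqrt(S)
        K = P / S
        for j in range(m):
            e = M[i, j] - a[j]
            W[i, j] = e * rs
            a[j] += K * e
        P = P - K * P
    return W, logdet


@njit(cache=False)
def _whiten_ouf(dt, R, M, sig2, tp, tv):
    n, m = M.shape
    W = np.empty((n, m))
    az = np.zeros(m)  # position component of the state mean, per column
    av = np.zeros(m)  # velocity component
    r1 = 1.0 / tp
    r2 = 1.0 / tv
    vz = sig2
    vv = sig2 * r1 * r2
    # P symmetric 2x2
    P00, P01, P11 = vz, 0.0, vv
    logdet = 0.0
    for i in range(n):
        if i > 0:
            d = dt[i - 1]
            if abs(r2 - r1) < 1e-10 * r2:
                r = 0.5 * (r1 + r2)
                e = math.exp(-r * d)
                f00 = e * (1.0 + r * d)
                f01 = e * d
                f10 = -e * r * r * d
                f11 = e * (1.0 - r * d)
            else:
                e1 = math.exp(-r1 * d)
                e2 = math.exp(-r2 * d)
                den = r2 - r1
                f00 = (r2 * e1 - r1 * e2) / den
                f01 = (e1 - e2) / den
                f10 = r1 * r2 * (e2 - e1) / den
                f11 = (r2 * e2 - r1 * e1) / den
            # propagate state mean for each column
            for j in range(m):
                z = az[j]
                v = av[j]
                az[j] = f00 * z + f01 * v
                av[j] = f10 * z + f11 * v
            # P <- Phi P Phi' + Q, Q = Pinf - Phi Pinf Phi'
            a00 = f00 * P00 + f01 * P01
            a01 = f00 * P01 + f01 * P11
            a10 = f10 * P00 + f11 * P01
            a11 = f10 * P01 + f11 * P11
            n00 = a00 * f00 + a01 * f01
            n01 = a00 * f10 + a01 * f11
            n11 = a10 * f10 + a11 * f11
            q00 = vz - (f00 * vz * f00 + f01 * vv * f01)
            q01 = -(f00 * vz * f10 + f01 * vv * f11)
            q11 = vv - (f10 * vz * f10 + f11 * vv * f11)
            P00 = n00 + q00
            P01 = n01 + q01
            P11 = n11 + q11
        S = P00 + R[i]
        logdet += math.log(S)
        rs = 1.0 / math.sqrt(S)
        K0 = P00 / S
        K1 = P01 / S
        for j in range(m):
            e = M[i, j] - az[j]
            W[i, j] = e * rs
            az[j] += K0 * e
            av[j] += K1 * e
        # P <- P - K (H P), H = [1 0]
        P11 = P11 - K1 * P01
        P01 = P01 - K1 * P00
        P00 = P00 - K0 * P00
    return W, logdet


def whiten(family: str, dt: np.ndarray, R: np.ndarray, M: np.ndarray,
           sig2: float, tau_pos: float = 0.0, tau_v: float = 0.0):
    """Whiten columns of ``M`` under the family's covariance; return (W, logdet)."""
    M = np.ascontiguousarray(M, dtype=np.float64)
    R = np.ascontiguousarray(R, dtype=np.float64)
    dt = np.ascontiguousarray(dt, dtype=np.float64)
    if family == "IID":
        return _whiten_iid(R, M, sig2)
    if family == "OU":
        return _whiten_ou(dt, R, M, sig2, tau_pos)
    if family == "OUF":
        return _whiten_ouf(dt, R, M, sig2, tau_pos, tau_v)
    raise ValueError(f"unknown family {family!r}")
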