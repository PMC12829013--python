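"""Bhattacharyya overlap between utilisation distributions and the
pairwise comparison design (same capture site; GPS-GPS, NB-NB, GPS-NB),
seasonal subsetting, and the debiased-vs-non-debiased bias proxy.
"""

from __future__ import annotations

import datetime as _dt
import logging
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .akde import akde
from .types import (
    BirdMetadata,
    LocationSeries,
    MetaEstimate,
    MovementModel,
    OverlapRecord,
    UtilisationDistribution,
)

logger = logging.getLogger(__name__)

SEASON_MONTHS = {"summer": (5, 6, 7), "winter": (11, 12, 1)}


def _grid_axes(ud: UtilisationDistribution):
    ny, nx = ud.density.shape
    gx = ud.x0 + (np.arange(nx) + 0.5) * ud.cell
    gy = ud.y0 + (np.arange(ny) + 0.5) * ud.cell
    # density row 0 is northernmost -> flip to ascending y
    return gx, gy, ud.density[::-1, :]


def _resample(ud: UtilisationDistribution, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    sx, sy, dens = _grid_axes(ud)
    interp = RegularGridInterpolator(
        (sy, sx), np.nan_to_num(dens), method="linear", bounds_error=False, fill_value=0.0
    )
    XX, YY = np.meshgrid(gx, gy)
    out = interp(np.column_stack([YY.ravel(), XX.ravel()])).reshape(YY.shape)
    return np.clip(out, 0.0, None)


def bhattacharyya(p: UtilisationDistribution, q: UtilisationDistribution) -> float:
    """Bhattacharyya coefficient sum sqrt(p q) * cell_area in [0, 1].

    The two UDs are bilinearly resampled onto a common grid (union extent,
    finer of the two cell sizes) and renormalised before integrating.
    """
    for ud in (p, q):
        if not 0.99 < ud.total_mass() < 1.01:
            raise ValueError("UD is not normalised")
    cell = min(p.cell, q.cell)
    x_lo = min(p.x0, q.x0)
    y_lo = min(p.y0, q.y0)
    x_hi = max(p.x0 + p.density.shape[1] * p.cell, q.x0 + q.density.shape[1] * q.cell)
    y_hi = max(p.y0 + p.density.shape[0] * p.cell, q.y0 + q.density.shape[0] * q.cell)
    nx = min(int(np.ceil((x_hi - x_lo) / cell)), 1200)
    ny = min(int(np.ceil((y_hi - y_lo) / cell)), 1200)
    cell_x = (x_hi - x_lo) / nx
    cell_y = (y_hi - y_lo) / ny
    gx = x_lo + (np.arange(nx) + 0.5) * cell_x
    gy = y_lo + (np.arange(ny) + 0.5) * cell_y
    dp = _resample(p, gx, gy)
    dq = _resample(q, gx, gy)
    area = cell_x * cell_y
    mp, mq = dp.sum() * area, dq.sum() * area
    if mp <= 0 or mq <= 0:
        return 0.0
    dp /= mp
    dq /= mq
    return float(np.clip(np.sqrt(dp * dq).sum() * area, 0.0, 1.0))


def seasonal_subset(series: LocationSeries, season: str) -> LocationSeries:
    """Restrict to summer (May-Jul) or winter (Nov-Jan) months; annual = identity."""
    if season == "annual":
        return series
    months = SEASON_MONTHS[season]
    obs_months = np.array(
        [_dt.datetime.fromtimestamp(t, tz=_dt.timezone.utc).month for t in series.t]
    )
    return series.take(np.isin(obs_months, months))


def pairwise_design(
    metadata: Sequence[BirdMetadata],
    uds: Dict[str, UtilisationDistribution],
    ess_min: float = 1.0,
) -> List[OverlapRecord]:
    """All unordered same-site pairs of UDs, classified by tracking method.

    A pair contributes only if both effective sample sizes (the pair ess is
    the min of the two ``dof_area`` values) reach ``ess_min``.
    """
    meta = {m.individual_id: m for m in metadata}
    ids = [i for i in sorted(uds) if i in meta]
    out: List[OverlapRecord] = []
    cls = {("gps", "gps"): "GPS-GPS", ("neckband", "neckband"): "NB-NB"}
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            ma, mb = meta[a], meta[b]
            if ma.capture_site != mb.capture_site:
                continue
            ua, ub = uds[a], uds[b]
            if ua.season != ub.season:
                continue
            ess = float(min(ua.dof_area, ub.dof_area))
            if not np.isfinite(ess) or ess < ess_min:
                continue
            klass = cls.get((ma.method, mb.method), "GPS-NB")
            out.append(
                OverlapRecord(
                    id_a=a,
                    id_b=b,
                    comparison_class=klass,
                    capture_site=ma.capture_site,
                    season=ua.season,
                    bc=bhattacharyya(ua, ub),
                    ess=ess,
                )
            )
    if not out:
        logger.warning("pairwise design produced no records (ess_min=%s)", ess_min)
    return out


def debias_contrast(
    series: LocationSeries,
    model: MovementModel,
    season: str = "annual",
    capture_site: str = "",
) -> Optional[OverlapRecord]:
    """Overlap between the debiased and non-debiased UD of one bird/season.

    High overlap means the debiasing weights barely moved the estimate,
    i.e. sampling was close to unbiased; low overlap flags reporting bias.
    Returns None (logged) when the seasonal subset has < 2 observations.
    """
    sub = seasonal_subset(series, season)
    if len(sub) < 2:
        logger.info("debias contrast skipped for %s/%s (<2 obs)", series.individual_id, season)
        return None
    ud_w = akde(sub, model, debias=True, season=season)
    ud_u = akde(sub, model, debias=False, season=season)
    return OverlapRecord(
        id_a=series.individual_id,
        id_b=series.individual_id,
        comparison_class="self-debias",
        capture_site=capture_site,
        season=season,
        bc=bhattacharyya(ud_w, ud_u),
        ess=float(model.ess_area),
    )


def summarize_overlap(
    records: Sequence[OverlapRecord],
    by=("season", "comparison_class"),
) -> List[MetaEstimate]:
    """Group means of the Bhattacharyya coefficient with 50/75/95% intervals.

    Estimated on the logit scale (respecting the [0, 1] bounds) with the
    random-effects machinery from :mod:`tandemtrack.population_meta`.
    """
    from .population_meta import meta_mean

    keys = sorted({tuple(getattr(r, f) for f in by) for r in records})
    out: List[MetaEstimate] = []
    for key in keys:
        vals = np.array(
            [r.bc for r in records if tuple(getattr(r, f) for f in by) == key]
        )
        est = meta_mean(vals, np.zeros(vals.size), scale="logit",
                        parameter="bc", group="/".join(str(k) for k in key))
        out.append(est)
    return out
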