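"""Filtering and censoring rules applied before model fitting.

All operations are pure (input series are never mutated), order-stable,
idempotent, and report how many records each rule removed so that the
audit counts always sum back to the input size.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .geo import geodesic_distance
from .types import BirdMetadata, LocationSeries, SECONDS_PER_DAY

logger = logging.getLogger(__name__)

#: Resight plausibility ceiling on mean ground speed: 3.65 m/s = 315.36 km/day.
RESIGHT_SPEED_CEILING = 3.65
#: GPS speed filter: reported airspeed mean + 3 SD (24.91 m/s) plus an assumed
#: maximum wind support of 15 m/s, rounded up to the nearest 5 m/s.
GPS_SPEED_VMAX = 40.0


def gps_speed_vmax(airspeed_mean_plus_3sd: float = 24.91, wind_support: float = 15.0,
                   round_to: float = 5.0) -> float:
    """Derive the GPS speed-filter ceiling from airspeed and wind assumptions."""
    raw = airspeed_mean_plus_3sd + wind_support
    return float(np.ceil(raw / round_to) * round_to)


def _utc_date(seconds: float) -> _dt.date:
    return _dt.datetime.fromtimestamp(seconds, tz=_dt.timezone.utc).date()


def _epoch(date: _dt.date) -> float:
    return _dt.datetime(date.year, date.month, date.day, tzinfo=_dt.timezone.utc).timestamp()


def censor_juveniles(
    series: Sequence[LocationSeries],
    metadata: Sequence[BirdMetadata],
    cutoff_year_offset: int = 1,
) -> Tuple[List[LocationSeries], Dict[str, int]]:
    """Drop juvenile observations before April 01 of the bird's second spring.

    "Second spring" is taken as April 01 of the ``cutoff_year_offset``-th
    calendar year after the capture (hatch) year — offset 1 for June-caught
    juveniles.  Adults pass through untouched; birds with unknown age pass
    through with a warning.  Returns the filtered series and per-bird
    removal counts.
    """
    by_id = {m.individual_id: m for m in metadata}
    out, removed = [], {}
    for s in series:
        m = by_id.get(s.individual_id)
        if m is None or m.age_at_capture not in ("juvenile", "adult"):
            logger.warning("unknown age for %s; passed through", s.individual_id)
            out.append(s)
            removed[s.individual_id] = 0
            continue
        if m.age_at_capture == "adult":
            out.append(s)
            removed[s.individual_id] = 0
            continue
        capture_year = int(str(m.capture_date)[:4])
        cutoff = _epoch(_dt.date(capture_year + cutoff_year_offset, 4, 1))
        keep = s.t >= cutoff
        removed[s.individual_id] = int((~keep).sum())
        out.append(s.take(keep))
    return out, removed


def censor_pairs(
    series: Sequence[LocationSeries],
    metadata: Sequence[BirdMetadata],
) -> Tuple[List[LocationSeries], List[str]]:
    """Keep one member per mated pair; return (series, censored ids).

    The retained member has the longer tracking duration; ties break on the
    higher observation count, then the lexicographically smaller id.
    """
    by_id = {s.individual_id: s for s in series}
    meta_by_id = {m.individual_id: m for m in metadata}
    censored: List[str] = []
    seen = set()
    for m in metadata:
        p = m.pair_partner_id
        if not p or m.individual_id in seen or p not in meta_by_id:
            continue
        seen.update({m.individual_id, p})
        sa, sb = by_id.get(m.individual_id), by_id.get(p)
        if sa is None or sb is None:
            if sa is None and sb is None:
                continue
            censored.append(m.individual_id if sa is None else p)
            continue
        key_a = (sa.duration, len(sa), sa.individual_id < sb.individual_id)
        key_b = (sb.duration, len(sb), sb.individual_id < sa.individual_id)
        loser = sb.individual_id if key_a > key_b else sa.individual_id
        censored.append(loser)
    kept = [s for s in series if s.individual_id not in set(censored)]
    return kept, censored


def dedupe_daily(series: LocationSeries) -> Tuple[LocationSeries, int]:
    """Keep at most one (the earliest) observation per UTC calendar day."""
    if len(series) == 0:
        return series, 0
    days = np.floor(series.t / SECONDS_PER_DAY).astype(np.int64)
    _, first_idx = np.unique(days, return_index=True)
    removed = len(series) - first_idx.size
    return series.take(np.sort(first_idx)), removed


def mean_ground_speed(series: LocationSeries) -> float:
    """Mean of geodesic segment speed (m/s) over consecutive observations.

    Returns NaN (flagged) for series with fewer than two observations.
    """
    if len(series) < 2:
        logger.warning("mean_ground_speed undefined for %s (<2 obs)", series.individual_id)
        return float("nan")
    d = geodesic_distance(series.lon[:-1], series.lat[:-1], series.lon[1:], series.lat[1:])
    dt = np.diff(series.t)
    return float(np.mean(np.asarray(d) / dt))


def flag_speeders(
    series: Sequence[LocationSeries], ceiling: float = RESIGHT_SPEED_CEILING
) -> List[str]:
    """Ids whose mean ground speed exceeds the resight plausibility ceiling.

    Flagged, not deleted: the screen is diagnostic.
    """
    return [
        s.individual_id
        for s in series
        if len(s) >= 2 and mean_ground_speed(s) > ceiling
    ]


def gps_speed_filter(
    series: LocationSeries, vmax: float = GPS_SPEED_VMAX
) -> Tuple[LocationSeries, int]:
    """Iteratively remove locations implying segment speeds above ``vmax``.

    At each pass the candidate whose single removal most reduces the summed
    speed excess is dropped (deterministic leave-one-out criterion), until
    no consecutive pair implies a speed above the ceiling.
    """
    idx = list(range(len(series)))
    removed = 0

    def seg_speeds(active: List[int]) -> np.ndarray:
        if len(active) < 2:
            return np.empty(0)
        lon, lat, t = series.lon[active], series.lat[active], series.t[active]
        d = np.atleast_1d(geodesic_distance(lon[:-1], lat[:-1], lon[1:], lat[1:]))
        return d / np.diff(t)

    while len(idx) >= 2:
        sp = seg_speeds(idx)
        if not np.any(sp > vmax):
            break
        excess = float(np.clip(sp - vmax, 0, None).sum())
        best_j, best_excess = None, excess
        # candidates: endpoints of any offending segment
        cand = sorted({j for k in np.flatnonzero(sp > vmax) for j in (k, k + 1)})
        for j in cand:
            trial = idx[:j] + idx[j + 1 :]
            e = float(np.clip(seg_speeds(trial) - vmax, 0, None).sum())
            if e < best_excess - 1e-12 or (best_j is None and e < excess):
                best_j, best_excess = j, e
        if best_j is None:
            break
        del idx[best_j]
        removed += 1
    return series.take(np.array(idx, dtype=int)), removed


def solar_noon_utc_seconds(lon: float) -> float:
    """Seconds after UTC midnight of local solar noon at longitude ``lon``.

    Uses mean solar time (12:00 UTC minus lon/15 hours); the equation of
    time (<= ~16 min) is ignored, which is negligible against a 24-h grid.
    """
    return ((12.0 - lon / 15.0) % 24.0) * 3600.0


def thin_to_solar_noon(series: LocationSeries) -> Tuple[LocationSeries, int]:
    """Keep the fix closest to local solar noon on each UTC day."""
    if len(series) == 0:
        return series, 0
    days = np.floor(series.t / SECONDS_PER_DAY).astype(np.int64)
    tod = series.t - days * SECONDS_PER_DAY
    noon = np.array([solar_noon_utc_seconds(l) for l in series.lon])
    dist = np.abs(tod - noon)
    dist = np.minimum(dist, SECONDS_PER_DAY - dist)  # wrap across midnight
    keep = []
    for day in np.unique(days):
        members = np.flatnonzero(days == day)
        keep.append(members[int(np.argmin(dist[members]))])
    keep = np.sort(np.asarray(keep))
    return series.take(keep), len(series) - keep.size


def remove_failed_fixes(series: LocationSeries) -> Tuple[LocationSeries, int]:
    """Drop fixes with zero satellites or missing coordinates."""
    ok = np.isfinite(series.lon) & np.isfinite(series.lat)
    if series.satellites is not None:
        sats = np.asarray(series.satellites, dtype=float)
        ok &= ~(sats == 0)
    removed = int((~ok).sum())
    if removed == len(series):
        logger.warning("all fixes invalid for %s", series.individual_id)
    return series.take(ok), removed


@dataclass
class AuditEntry:
    individual_id: str
    rule: str
    removed: int


def preprocess_gps(series: LocationSeries, vmax: float = GPS_SPEED_VMAX):
    """Standard GPS chain: failed-fix removal, speed filter, solar-noon thinning."""
    audit: List[AuditEntry] = []
    s, r = remove_failed_fixes(series)
    audit.append(AuditEntry(series.individual_id, "failed_fixes", r))
    s, r = gps_speed_filter(s, vmax)
    audit.append(AuditEntry(series.individual_id, "speed_filter", r))
    s, r = thin_to_solar_noon(s)
    audit.append(AuditEntry(series.individual_id, "solar_noon_thin", r))
    return s, audit


def preprocess_resights(series: LocationSeries):
    """Standard resight chain: daily dedup plus the mean-speed screen."""
    audit: List[AuditEntry] = []
    s, r = dedupe_daily(series)
    audit.append(AuditEntry(series.individual_id, "daily_dedup", r))
    return s, audit
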