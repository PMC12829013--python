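"""Readers/writers for tracking tables and gridded utilisation distributions.

Location tables are plain CSV (UTF-8, comma-separated, ISO-8601 UTC
timestamps) with a configurable column map; the defaults follow Movebank
conventions.  Utilisation distributions are written as ESRI ASCII grids — a
plain-text header (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value)
followed by rows of cell values — which any GIS can open.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .geo import ProjectionSpec
from .types import BirdMetadata, LocationSeries, UtilisationDistribution

logger = logging.getLogger(__name__)

#: Default column map for tracking CSVs (Movebank-style names).
DEFAULT_SCHEMA: Dict[str, str] = {
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "id": "individual-local-identifier",
    "error_radius": "error-radius",  # optional
    "satellites": "gps-satellite-count",  # optional
}

_NOON_SECONDS = 12 * 3600.0


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


def _to_utc_seconds(values: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(values, utc=True, errors="coerce", format="mixed")
    ns = ts.to_numpy(dtype="datetime64[ns]").astype("int64").astype(float) / 1e9
    return np.where(pd.isna(ts).to_numpy(), np.nan, ns)


def read_locations(
    path,
    schema: Optional[Dict[str, str]] = None,
    source: str = "gps",
) -> List[LocationSeries]:
    """Read a tracking CSV into one time-sorted :class:`LocationSeries` per bird.

    Rows with unparseable timestamps or coordinates are dropped and counted
    in the log.  Resight rows carrying a date but no time-of-day are placed
    at 12:00 UTC.  Exact duplicate timestamps within a bird keep the first
    occurrence.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("empty location file: %s", path)
        return []
    for key in ("timestamp", "lon", "lat", "id"):
        if cols[key] not in df.columns:
            raise SchemaError(f"missing mandatory column '{cols[key]}' (role: {key})")

    t = _to_utc_seconds(df[cols["timestamp"]])
    # date-only resights: pandas parses "2020-01-05" to midnight; shift to noon
    if source == "resight":
        raw = df[cols["timestamp"]].astype(str)
        date_only = ~raw.str.contains(":", na=False)
        t = np.where(date_only & np.isfinite(t), t + _NOON_SECONDS, t)
    lon = pd.to_numeric(df[cols["lon"]], errors="coerce").to_numpy()
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce").to_numpy()
    err = (
        pd.to_numeric(df[cols["error_radius"]], errors="coerce").to_numpy()
        if cols.get("error_radius") in df.columns
        else np.zeros(len(df))
    )
    sats = (
        pd.to_numeric(df[cols["satellites"]], errors="coerce").to_numpy()
        if cols.get("satellites") in df.columns
        else None
    )

    ok = np.isfinite(t) & np.isfinite(lon) & np.isfinite(lat) & (np.abs(lat) <= 90)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("%s: dropped %d unparseable rows", path, dropped)

    out: List[LocationSeries] = []
    ids = df[cols["id"]].astype(str).to_numpy()
    for bird in sorted(pd.unique(ids[ok])):
        m = ok & (ids == bird)
        order = np.argsort(t[m], kind="stable")
        tb = t[m][order]
        keep = np.concatenate([[True], np.diff(tb) > 0])
        sel = np.flatnonzero(m)[order][keep]
        out.append(
            LocationSeries(
                individual_id=bird,
                t=t[sel],
                lon=lon[sel],
                lat=lat[sel],
                error_radius=np.nan_to_num(err[sel], nan=0.0),
                source=source,
                satellites=None if sats is None else sats[sel],
            )
        )
    return out


def write_locations(series: Iterable[LocationSeries], path) -> None:
    """Write series back to CSV in the default schema (lossless round trip)."""
    rows = []
    for s in series:
        ts = pd.to_datetime(np.round(s.t, 6), unit="s", utc=True)
        for i in range(len(s)):
            rows.append(
                {
                    DEFAULT_SCHEMA["timestamp"]: ts[i].isoformat(),
                    DEFAULT_SCHEMA["lon"]: repr(float(s.lon[i])),
                    DEFAULT_SCHEMA["lat"]: repr(float(s.lat[i])),
                    DEFAULT_SCHEMA["id"]: s.individual_id,
                    DEFAULT_SCHEMA["error_radius"]: float(s.error_radius[i]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> List[BirdMetadata]:
    """Read the deployment metadata CSV (id, site, date, sex, age, method, partner)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    need = {"individual_id", "capture_site", "capture_date"}
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"metadata missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            BirdMetadata(
                individual_id=str(r["individual_id"]),
                capture_site=str(r["capture_site"]),
                capture_date=str(r["capture_date"]),
                sex=str(r.get("sex", "u") or "u"),
                age_at_capture=str(r.get("age_at_capture", "adult") or "adult"),
                method=str(r.get("method", "gps") or "gps"),
                pair_partner_id=(str(r["pair_partner_id"]) or None)
                if "pair_partner_id" in df.columns
                else None,
            )
        )
    ids = [m.individual_id for m in out]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate individual_id in metadata")
    by_id = {m.individual_id: m for m in out}
    for m in out:
        p = m.pair_partner_id
        if p and p in by_id and by_id[p].pair_partner_id not in (None, "", m.individual_id):
            raise ValueError(f"asymmetric pair link {m.individual_id} <-> {p}")
    return out


def write_metadata(meta: Iterable[BirdMetadata], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": m.individual_id,
                "capture_site": m.capture_site,
                "capture_date": m.capture_date,
                "sex": m.sex,
                "age_at_capture": m.age_at_capture,
                "method": m.method,
                "pair_partner_id": m.pair_partner_id or "",
            }
            for m in meta
        ]
    ).to_csv(path, index=False)


def centroid_projection(series: Sequence[LocationSeries]) -> ProjectionSpec:
    """Equal-area frame centred on the centroid of all input locations."""
    lons = np.concatenate([s.lon for s in series])
    lats = np.concatenate([s.lat for s in series])
    # average on the unit sphere so longitude wrap-around is safe
    lam, phi = np.radians(lons), np.radians(lats)
    v = np.array(
        [np.mean(np.cos(phi) * np.cos(lam)), np.mean(np.cos(phi) * np.sin(lam)), np.mean(np.sin(phi))]
    )
    v = v / np.linalg.norm(v)
    return ProjectionSpec(
        reference_lon=float(np.degrees(np.arctan2(v[1], v[0]))),
        reference_lat=float(np.degrees(np.arcsin(v[2]))),
    )


def project(series: LocationSeries, spec: ProjectionSpec) -> LocationSeries:
    """Fill planar x/y (metres) from lon/lat in the given equal-area frame."""
    x, y = spec.forward(series.lon, series.lat)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite projected coordinates")
    out = series.take(np.arange(len(series)))
    out.x = np.asarray(x, dtype=float)
    out.y = np.asarray(y, dtype=float)
    return out


# ---------------------------------------------------------------- rasters


def write_ud_raster(ud: UtilisationDistribution, path, nodata: float = -9999.0) -> None:
    """Write a UD as an ESRI ASCII grid (density in m^-2, NaN -> NODATA)."""
    dens = ud.density
    nrows, ncols = dens.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {ud.x0!r}\n")
        fh.write(f"yllcorner {ud.y0!r}\n")
        fh.write(f"cellsize {ud.cell!r}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in dens:
            vals = np.where(np.isnan(row), nodata, row)
            fh.write(" ".join(repr(float(v)) for v in vals) + "\n")


def read_ud_raster(path) -> UtilisationDistribution:
    """Read an ESRI ASCII grid back into a :class:`UtilisationDistribution`."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[6:]).reshape(nrows, ncols)
    data = np.where(data == nodata, np.nan, data)
    return UtilisationDistribution(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        density=data,
    )


def write_table(records: Sequence, path) -> None:
    """Write a list of dataclass records (or dicts) as a CSV with header."""
    if not records:
        raise ValueError("empty record list")
    if hasattr(records[0], "__dataclass_fields__"):
        import dataclasses

        rows = [dataclasses.asdict(r) for r in records]
    else:
        rows = list(records)
    pd.DataFrame(rows).to_csv(path, index=False)
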