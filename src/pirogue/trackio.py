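"""Reading, writing and summarizing GPS fishing trips.

Trips are stored column-wise (numpy arrays of times/coordinates) for speed,
with a :class:`Fix` view for point-wise access.  Supported interchange
formats are GPX 1.1 tracks and a flat CSV schema
(``trip_id, time, lat, lon [, gear, state]``).
"""

from __future__ import annotations

import io
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._geo import haversine_m

#: The seven gear codes of the study fleet.
GEARS = ("SCG", "SG", "MCG", "PS", "HL", "LL", "BG")

GEAR_NAMES = {
    "SCG": "sardine circling gillnet",
    "SG": "surface drifting gillnet",
    "MCG": "mullet circling gillnet",
    "PS": "purse seine",
    "HL": "handline",
    "LL": "longline",
    "BG": "bottom gillnet",
}

__all__ = [
    "GEARS",
    "GEAR_NAMES",
    "Fix",
    "Trip",
    "LandingSite",
    "TripSummary",
    "read_gpx",
    "read_track_csv",
    "write_track_csv",
    "read_sites_csv",
    "trip_summary",
]


class Fix(NamedTuple):
    """A single timestamped WGS84 position."""

    time: np.datetime64
    lat: float
    lon: float


@dataclass(frozen=True)
class LandingSite:
    site_id: str
    lat: float
    lon: float

    def __post_init__(self):
        _check_coords(np.asarray([self.lat]), np.asarray([self.lon]), f"site {self.site_id}")


@dataclass
class Trip:
    """An ordered sequence of fixes with gear-type metadata.

    ``lat``/``lon`` may be NaN (paired) on regularized trips to mark grid
    positions that fall inside a recording gap; raw trips have no NaNs.
    ``interval_s`` is set once the trip is on a strictly regular grid.
    """

    trip_id: str
    times: np.ndarray  # datetime64[s], strictly increasing
    lat: np.ndarray
    lon: np.ndarray
    gear: str | None = None
    landing_site_id: str | None = None
    interval_s: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        n = len(self.times)
        if not (len(self.lat) == len(self.lon) == n):
            raise ValueError(f"trip {self.trip_id}: times/lat/lon length mismatch")
        if n < 2:
            raise ValueError(f"trip {self.trip_id}: a trip needs at least 2 fixes, got {n}")
        dt = np.diff(self.times.astype("int64"))
        if np.any(dt <= 0):
            raise ValueError(f"trip {self.trip_id}: fix times must be strictly increasing")
        if self.gear is not None and self.gear not in GEARS:
            raise ValueError(
                f"trip {self.trip_id}: unknown gear {self.gear!r}; expected one of {GEARS}"
            )
        if np.any(np.isnan(self.lat) != np.isnan(self.lon)):
            raise ValueError(f"trip {self.trip_id}: lat/lon missingness must be paired")
        ok = ~np.isnan(self.lat)
        _check_coords(self.lat[ok], self.lon[ok], f"trip {self.trip_id}")

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.lat)

    @property
    def fixes(self) -> list[Fix]:
        return [Fix(t, la, lo) for t, la, lo in zip(self.times, self.lat, self.lon)]

    def slice(self, idx) -> "Trip":
        """New Trip restricted to integer / boolean index ``idx`` (order kept)."""
        return replace(
            self,
            times=self.times[idx],
            lat=self.lat[idx],
            lon=self.lon[idx],
            interval_s=None,
        )


@dataclass(frozen=True)
class TripSummary:
    trip_id: str
    duration_h: float
    total_distance_km: float
    n_fixes: int


def _check_coords(lat: np.ndarray, lon: np.ndarray, where: str, rows=None) -> None:
    bad_lat = (lat < -90.0) | (lat > 90.0) | ~np.isfinite(lat)
    bad_lon = (lon < -180.0) | (lon > 180.0) | ~np.isfinite(lon)
    if np.any(bad_lat):
        i = int(np.argmax(bad_lat))
        row = rows[i] if rows is not None else i
        raise ValueError(f"{where}: latitude out of range [-90, 90] at row {row}: {lat[i]}")
    if np.any(bad_lon):
        i = int(np.argmax(bad_lon))
        row = rows[i] if rows is not None else i
        raise ValueError(f"{where}: longitude out of range [-180, 180] at row {row}: {lon[i]}")


# ---------------------------------------------------------------------------
# GPX
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_gpx(path) -> list[Trip]:
    """Read GPX 1.1 tracks into Trips, one Trip per ``<trk>``.

    Multiple ``<trkseg>`` within one track are concatenated (segments are
    receiver power cycles, not trip boundaries).  Fixes are sorted by time
    and exact duplicate timestamps are collapsed to the first occurrence.
    Track points without ``<time>`` reject the file; tracks without points
    are skipped with a warning.
    """
    tree = ET.parse(str(path))
    root = tree.getroot()
    trips: list[Trip] = []
    trk_index = 0
    for trk in root.iter():
        if _local(trk.tag) != "trk":
            continue
        trk_index += 1
        name = None
        times, lats, lons = [], [], []
        pt_index = 0
        for el in trk.iter():
            tag = _local(el.tag)
            if tag == "name" and name is None and el.text:
                name = el.text.strip()
            elif tag == "trkpt":
                pt_index += 1
                t_el = next((c for c in el if _local(c.tag) == "time"), None)
                if t_el is None or not (t_el.text or "").strip():
                    raise ValueError(
                        f"{path}: track {trk_index} point {pt_index} "
                        f"(lat={el.get('lat')}, lon={el.get('lon')}) has no <time>"
                    )
                ts = pd.Timestamp(t_el.text.strip())
                if ts.tzinfo is not None:
                    ts = ts.tz_convert("UTC").tz_localize(None)
                times.append(np.datetime64(ts, "s"))
                lats.append(float(el.get("lat")))
                lons.append(float(el.get("lon")))
        trip_id = name or f"trk{trk_index}"
        if not times:
            warnings.warn(f"{path}: track {trip_id!r} has no points; skipped")
            continue
        order = np.argsort(np.asarray(times, dtype="datetime64[s]"), kind="stable")
        t = np.asarray(times, dtype="datetime64[s]")[order]
        la = np.asarray(lats)[order]
        lo = np.asarray(lons)[order]
        keep = np.concatenate([[True], np.diff(t.astype("int64")) > 0])
        trips.append(Trip(trip_id=trip_id, times=t[keep], lat=la[keep], lon=lo[keep]))
    return trips


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("trip_id", "time", "lat", "lon")


def read_track_csv(path, column_map: dict | None = None) -> list[Trip]:
    """Read trips from CSV with columns trip_id, time, lat, lon [, gear].

    ``column_map`` maps the canonical names to the file's actual column
    names.  Rows are grouped by trip_id (order of first appearance), sorted
    by time within a trip, duplicate timestamps collapsed to the first.
    """
    column_map = column_map or {}
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty file, no trips read")
        return []
    if df.empty:
        warnings.warn(f"{path}: no data rows, no trips read")
        return []
    cols = {k: column_map.get(k, k) for k in (*_CSV_COLUMNS, "gear")}
    for k in _CSV_COLUMNS:
        if cols[k] not in df.columns:
            raise ValueError(f"{path}: required column {cols[k]!r} not found")
    times = pd.to_datetime(df[cols["time"]], utc=True, errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise ValueError(f"{path}: unparseable timestamp at row {row}: {df[cols['time']][row]!r}")
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce").to_numpy()
    lon = pd.to_numeric(df[cols["lon"]], errors="coerce").to_numpy()
    _check_coords(lat, lon, str(path), rows=df.index.to_numpy())
    df = df.assign(
        _t=times.dt.tz_convert("UTC").dt.tz_localize(None).astype("datetime64[s]"),
        _lat=lat,
        _lon=lon,
    )
    trips = []
    for trip_id, g in df.groupby(cols["trip_id"], sort=False):
        g = g.sort_values("_t", kind="stable")
        keep = np.concatenate([[True], np.diff(g["_t"].to_numpy().astype("int64")) > 0])
        g = g[keep]
        gear = None
        if cols["gear"] in g.columns:
            vals = g[cols["gear"]].dropna().unique()
            gear = str(vals[0]) if len(vals) else None
        trips.append(
            Trip(
                trip_id=str(trip_id),
                times=g["_t"].to_numpy(),
                lat=g["_lat"].to_numpy(),
                lon=g["_lon"].to_numpy(),
                gear=gear,
            )
        )
    return trips


def write_track_csv(trips: Iterable[Trip], path, labels: dict | None = None) -> None:
    """Write trips (optionally with per-fix state labels) to CSV.

    ``labels`` maps trip_id to a sequence of state names.  A sequence of
    length ``n_fixes - 1`` (per-interval labels) is accepted and extended to
    the last fix by repeating the final label; any other mismatch is an
    error.  The file round-trips through :func:`read_track_csv` at 1 s /
    1e-6 degree precision.
    """
    frames = []
    for trip in trips:
        d = {
            "trip_id": trip.trip_id,
            "time": pd.Series(trip.times).dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "lat": np.round(trip.lat, 6),
            "lon": np.round(trip.lon, 6),
        }
        if trip.gear is not None:
            d["gear"] = trip.gear
        if labels is not None and trip.trip_id in labels:
            lab = list(labels[trip.trip_id])
            if len(lab) == trip.n_fixes - 1:
                lab = lab + [lab[-1]]
            if len(lab) != trip.n_fixes:
                raise ValueError(
                    f"trip {trip.trip_id}: {len(lab)} labels for {trip.n_fixes} fixes"
                )
            d["state"] = lab
        frames.append(pd.DataFrame(d))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_CSV_COLUMNS)
    out.to_csv(path, index=False, float_format="%.6f")


def read_sites_csv(path) -> list[LandingSite]:
    """Read landing sites from CSV with columns site_id, lat, lon."""
    df = pd.read_csv(path)
    for c in ("site_id", "lat", "lon"):
        if c not in df.columns:
            raise ValueError(f"{path}: required column {c!r} not found")
    return [
        LandingSite(site_id=str(r.site_id), lat=float(r.lat), lon=float(r.lon))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def trip_summary(trip: Trip) -> TripSummary:
    """Duration (h) and total great-circle path length (km) of a trip."""
    ok = ~trip.missing
    lat, lon = trip.lat[ok], trip.lon[ok]
    dist_m = float(np.sum(haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:]))) if ok.sum() >= 2 else 0.0
    dur_s = float((trip.times[-1] - trip.times[0]) / np.timedelta64(1, "s"))
    return TripSummary(
        trip_id=trip.trip_id,
        duration_h=dur_s / 3600.0,
        total_distance_km=dist_m / 1000.0,
        n_fixes=trip.n_fixes,
    )
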