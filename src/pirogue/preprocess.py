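"""Track cleaning, regularization and derivation of HMM observations.

The cleaning rules: drop fixes within a 3 km buffer of landing sites, drop
fixes implying arrival speeds above 50 km/h, then resample onto a strictly
regular time grid by constant-speed great-circle interpolation.  From a
regular trip, step lengths (m) and turning angles (rad, left-positive) are
derived as the observation series for the state model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._geo import haversine_m, initial_bearing, interpolate_great_circle, wrap_angle
from .trackio import LandingSite, Trip

__all__ = [
    "StepSeries",
    "EmptyTripError",
    "trim_landing_buffer",
    "speed_filter",
    "regularize",
    "decimate",
    "steps_and_angles",
    "speed_series",
]


class EmptyTripError(ValueError):
    """Raised when a cleaning step leaves fewer than 2 fixes."""


@dataclass
class StepSeries:
    """Regular-interval observation series for one trip.

    For M grid fixes there are M-1 steps; the angle at interior fix i
    (i = 1..M-2) is stored at ``angle[i-1]``.  NaN marks a missing element
    (gap in the grid, or an angle undefined because an adjacent step is 0).
    """

    trip_id: str
    interval_s: float
    t0: np.datetime64
    step: np.ndarray  # metres, length M-1, NaN = missing
    angle: np.ndarray  # radians in (-pi, pi], length M-2, NaN = missing
    gear: str | None = None

    def __post_init__(self):
        self.step = np.asarray(self.step, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if len(self.angle) != max(len(self.step) - 1, 0):
            raise ValueError("angle must have one fewer element than step")
        with np.errstate(invalid="ignore"):
            if np.any(self.step < 0):
                raise ValueError("negative step length")
            if np.any((self.angle <= -np.pi) | (self.angle > np.pi)):
                raise ValueError("angle outside (-pi, pi]")

    @property
    def n_obs(self) -> int:
        return len(self.step)

    @property
    def times(self) -> np.ndarray:
        """Grid fix times (length M)."""
        n = len(self.step) + 1
        return self.t0 + (np.arange(n) * self.interval_s).astype("timedelta64[s]")


def trim_landing_buffer(
    trip: Trip, sites: Sequence[LandingSite], radius_km: float = 3.0
) -> Trip:
    """Remove fixes strictly within ``radius_km`` of any landing site.

    The rule is strict ("within"): a fix exactly at the radius is retained.
    """
    if not sites:
        raise ValueError("trim_landing_buffer needs at least one landing site")
    dmin = np.full(trip.n_fixes, np.inf)
    for s in sites:
        d = haversine_m(trip.lat, trip.lon, s.lat, s.lon)
        dmin = np.minimum(dmin, np.asarray(d))
    keep = ~(dmin < radius_km * 1000.0)
    keep &= ~trip.missing  # missing fixes have no position; drop them too
    if keep.sum() < 2:
        raise EmptyTripError(
            f"trip {trip.trip_id}: fewer than 2 fixes remain outside the "
            f"{radius_km} km landing buffer"
        )
    return trip.slice(keep)


def speed_filter(trip: Trip, vmax_kmh: float = 50.0) -> Trip:
    """Remove fixes whose arrival speed from the last retained fix exceeds vmax.

    Forward sweep anchored on the first fix: when a fix is removed the next
    fix is re-evaluated against the previous retained one, so one outlier
    cannot poison two speeds.
    """
    if trip.n_fixes < 2:
        raise ValueError(f"trip {trip.trip_id}: speed_filter needs at least 2 fixes")
    t = trip.times.astype("int64")
    keep = np.zeros(trip.n_fixes, dtype=bool)
    keep[0] = True
    last = 0
    vmax_ms = vmax_kmh / 3.6
    for i in range(1, trip.n_fixes):
        d = haversine_m(trip.lat[last], trip.lon[last], trip.lat[i], trip.lon[i])
        if d / (t[i] - t[last]) <= vmax_ms:
            keep[i] = True
            last = i
    return trip.slice(keep)


def regularize(trip: Trip, interval_s: float, max_gap_s: float | None = None) -> Trip:
    """Resample onto the grid t0, t0+interval, ... (constant-speed interpolation).

    Each grid position is interpolated along the great-circle segment
    between the bracketing original fixes with along-segment fraction equal
    to the elapsed-time fraction.  Grid points falling inside an original
    gap longer than ``max_gap_s`` (default 10x the target interval) are
    emitted as missing (NaN) rather than interpolated.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    if trip.n_fixes < 2:
        raise ValueError(f"trip {trip.trip_id}: regularize needs at least 2 fixes")
    if max_gap_s is None:
        max_gap_s = 10.0 * interval_s
    t = trip.times.astype("int64").astype(float)
    n_grid = int(np.floor((t[-1] - t[0]) / interval_s)) + 1
    grid = t[0] + interval_s * np.arange(n_grid)
    # bracketing original segment for each grid time
    seg = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, trip.n_fixes - 2)
    lat_out = np.empty(n_grid)
    lon_out = np.empty(n_grid)
    gap_len = t[seg + 1] - t[seg]
    on_fix = grid == t[seg]
    src_missing = trip.missing
    for i in range(n_grid):
        j = seg[i]
        if on_fix[i]:
            lat_out[i], lon_out[i] = trip.lat[j], trip.lon[j]
            continue
        if gap_len[i] > max_gap_s or src_missing[j] or src_missing[j + 1]:
            lat_out[i] = lon_out[i] = np.nan
            continue
        frac = (grid[i] - t[j]) / gap_len[i]
        lat_out[i], lon_out[i] = interpolate_great_circle(
            trip.lat[j], trip.lon[j], trip.lat[j + 1], trip.lon[j + 1], frac
        )
    times_out = trip.times[0] + np.arange(n_grid) * np.timedelta64(int(interval_s), "s") \
        if float(interval_s).is_integer() else grid.astype("datetime64[s]")
    return replace(
        trip, times=times_out, lat=lat_out, lon=lon_out, interval_s=float(interval_s)
    )


def decimate(trip: Trip, factor: int) -> Trip:
    """Keep every ``factor``-th fix of a regular trip (grid spacing scales)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if trip.interval_s is None:
        raise ValueError(
            f"trip {trip.trip_id}: decimate requires a regular trip; run regularize first"
        )
    if factor == 1:
        return replace(trip)
    idx = np.arange(0, trip.n_fixes, int(factor))
    if len(idx) < 2:
        raise EmptyTripError(
            f"trip {trip.trip_id}: decimation by {factor} leaves a single fix"
        )
    out = trip.slice(idx)
    out.interval_s = trip.interval_s * int(factor)
    return out


def steps_and_angles(trip: Trip) -> StepSeries:
    """Derive the observation series (steps in m, turning angles in rad).

    Angles are left-positive: turning from due east to due north is +pi/2.
    The angle at an interior fix is missing when either adjacent step has
    zero length (stationary jitter must not masquerade as straight travel)
    or when any of the three fixes involved is missing.
    """
    if trip.interval_s is None:
        raise ValueError(
            f"trip {trip.trip_id}: steps_and_angles requires a regular trip"
        )
    if trip.n_fixes < 2:
        raise ValueError(f"trip {trip.trip_id}: need at least 2 fixes")
    la, lo = trip.lat, trip.lon
    step = np.asarray(haversine_m(la[:-1], lo[:-1], la[1:], lo[1:]), dtype=float)
    miss = trip.missing
    step[miss[:-1] | miss[1:]] = np.nan
    if trip.n_fixes >= 3:
        with np.errstate(invalid="ignore"):
            bearing = np.asarray(initial_bearing(la[:-1], lo[:-1], la[1:], lo[1:]))
            angle = wrap_angle(bearing[:-1] - bearing[1:])
            bad = (
                np.isnan(step[:-1])
                | np.isnan(step[1:])
                | (step[:-1] == 0.0)
                | (step[1:] == 0.0)
            )
        angle = np.where(bad, np.nan, angle)
    else:
        angle = np.empty(0)
    return StepSeries(
        trip_id=trip.trip_id,
        interval_s=float(trip.interval_s),
        t0=trip.times[0],
        step=step,
        angle=angle,
        gear=trip.gear,
    )


def speed_series(series: StepSeries) -> np.ndarray:
    """Per-interval speeds in km/h (NaN where the step is missing)."""
    return series.step / series.interval_s * 3.6
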