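"""Spherical geometry primitives shared by the whole package.

A single convention is used everywhere: great-circle (haversine) arithmetic
on a sphere of radius 6,371,000 m.  Bearings are radians clockwise from
north; turning angles are counterclockwise-positive (a left turn is > 0).
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "initial_bearing",
    "destination",
    "interpolate_great_circle",
    "wrap_angle",
]


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between WGS84 points (degrees).

    Accepts scalars or numpy arrays (broadcast).
    """
    p1 = np.radians(np.asarray(lat1, dtype=float))
    p2 = np.radians(np.asarray(lat2, dtype=float))
    dphi = p2 - p1
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    return d if d.ndim else float(d)


def initial_bearing(lat1, lon1, lat2, lon2):
    """Initial bearing (radians, clockwise from north, in (-pi, pi])."""
    p1 = np.radians(np.asarray(lat1, dtype=float))
    p2 = np.radians(np.asarray(lat2, dtype=float))
    dlmb = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    y = np.sin(dlmb) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlmb)
    b = np.arctan2(y, x)
    return b if b.ndim else float(b)


def destination(lat, lon, bearing_rad, distance_m):
    """Dead-reckoning destination point (scalar, degrees in / degrees out)."""
    delta = distance_m / EARTH_RADIUS_M
    phi1 = math.radians(lat)
    lmb1 = math.radians(lon)
    sin_phi2 = (
        math.sin(phi1) * math.cos(delta)
        + math.cos(phi1) * math.sin(delta) * math.cos(bearing_rad)
    )
    phi2 = math.asin(max(-1.0, min(1.0, sin_phi2)))
    lmb2 = lmb1 + math.atan2(
        math.sin(bearing_rad) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * sin_phi2,
    )
    lon2 = math.degrees(lmb2)
    if lon2 > 180.0:
        lon2 -= 360.0
    elif lon2 <= -180.0:
        lon2 += 360.0
    return math.degrees(phi2), lon2


def interpolate_great_circle(lat1, lon1, lat2, lon2, frac):
    """Point at fraction ``frac`` along the great circle from point 1 to 2.

    ``frac`` may be a scalar or an array; fraction 0 is point 1, fraction 1
    is point 2.  Degenerate (identical) endpoints return point 1.
    """
    frac = np.asarray(frac, dtype=float)
    p1 = np.radians([lat1, lon1])
    p2 = np.radians([lat2, lon2])
    v1 = np.array(
        [math.cos(p1[0]) * math.cos(p1[1]), math.cos(p1[0]) * math.sin(p1[1]), math.sin(p1[0])]
    )
    v2 = np.array(
        [math.cos(p2[0]) * math.cos(p2[1]), math.cos(p2[0]) * math.sin(p2[1]), math.sin(p2[0])]
    )
    dot = float(np.clip(np.dot(v1, v2), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        lat = np.full_like(frac, lat1, dtype=float)
        lon = np.full_like(frac, lon1, dtype=float)
        return (float(lat), float(lon)) if frac.ndim == 0 else (lat, lon)
    so = math.sin(omega)
    a = np.sin((1.0 - frac) * omega) / so
    b = np.sin(frac * omega) / so
    v = np.outer(a, v1) + np.outer(b, v2)
    lat = np.degrees(np.arctan2(v[:, 2], np.hypot(v[:, 0], v[:, 1])))
    lon = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    if frac.ndim == 0:
        return float(lat[0]), float(lon[0])
    return lat, lon


def wrap_angle(theta):
    """Wrap angles to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    w = np.angle(np.exp(1j * theta))
    # np.angle yields [-pi, pi]; fold the open lower edge onto +pi
    w = np.where(w == -np.pi, np.pi, w)
    return w if w.ndim else float(w)
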