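"""Spherical-earth geodesy helpers.

All distances use the haversine formula on a sphere of radius 6371.0 km;
the same convention is used everywhere in the package (particle speeds,
medoid selection, uncertainty quantiles, synthetic-track generation).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def normalize_lon(lon):
    """Wrap longitudes into the half-open interval [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def destination(lon, lat, bearing_deg, distance_km):
    """Destination point along a great circle.

    Starting at (lon, lat) degrees, travel `distance_km` on initial bearing
    `bearing_deg` (clockwise from north). Returns (lon, lat) in degrees with
    longitude normalized to [-180, 180).
    """
    lon1 = np.radians(np.asarray(lon, dtype=float))
    lat1 = np.radians(np.asarray(lat, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    d = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(d) + np.cos(lat1) * np.sin(d) * np.cos(brg))
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(d) * np.cos(lat1),
        np.cos(d) - np.sin(lat1) * np.sin(lat2),
    )
    return normalize_lon(np.degrees(lon2)), np.degrees(lat2)
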