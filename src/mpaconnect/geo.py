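"""Spherical-earth geometry helpers.

All distances use a spherical earth of radius 6371 km, the standard
convention for great-circle larval dispersal distances.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
EARTH_RADIUS_KM = EARTH_RADIUS_M / 1000.0

#: meters per degree of latitude (and of longitude at the equator)
METERS_PER_DEGREE = np.pi * EARTH_RADIUS_M / 180.0  # 111194.9266...


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def meters_per_degree_lon(lat_deg):
    """Length of one degree of longitude (m) at the given latitude."""
    return METERS_PER_DEGREE * np.cos(np.radians(np.asarray(lat_deg, dtype=float)))


def cell_areas_km2(lon_axis: np.ndarray, lat_axis: np.ndarray) -> np.ndarray:
    """Spherical areas (km^2) of regular lon/lat cells, shape (nlat, nlon).

    Cell edges are taken halfway between successive centers; end cells are
    symmetric. Area = R^2 * dlam * (sin(phi2) - sin(phi1)).
    """
    lon_axis = np.asarray(lon_axis, dtype=float)
    lat_axis = np.asarray(lat_axis, dtype=float)
    dlon = np.gradient(lon_axis)
    lat_edges = _edges(lat_axis)
    sin_edges = np.sin(np.radians(lat_edges))
    band = EARTH_RADIUS_KM ** 2 * np.diff(sin_edges)  # per-latitude strip, unit lon rad
    return band[:, None] * np.radians(dlon)[None, :]


def _edges(centers: np.ndarray) -> np.ndarray:
    mid = 0.5 * (centers[:-1] + centers[1:])
    first = centers[0] - (mid[0] - centers[0]) if len(centers) > 1 else centers[0] - 0.5
    last = centers[-1] + (centers[-1] - mid[-1]) if len(centers) > 1 else centers[-1] + 0.5
    return np.concatenate([[first], mid, [last]])
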