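"""Planar projection helpers.

All analysis distances (250 m grid cells, 250 m structure buffers, speed
filtering) are metric, so the package works in planar metres throughout.
Longitude/latitude input is converted with an equirectangular projection
centred on the colony; over a study region spanning a few degrees (e.g. a
continental-shelf embayment) the distortion is well below GPS error.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def project_lonlat(lon, lat, origin_lon: float, origin_lat: float):
    """Project lon/lat (degrees) to planar metres, equirectangular about origin.

    Returns ``(x, y)`` arrays; x east, y north, origin at ``(0, 0)``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    k = np.cos(np.deg2rad(origin_lat)) * EARTH_RADIUS_M
    x = np.deg2rad(lon - origin_lon) * k
    y = np.deg2rad(lat - origin_lat) * EARTH_RADIUS_M
    return x, y


def unproject_xy(x, y, origin_lon: float, origin_lat: float):
    """Inverse of :func:`project_lonlat`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = np.cos(np.deg2rad(origin_lat)) * EARTH_RADIUS_M
    lon = origin_lon + np.rad2deg(x / k)
    lat = origin_lat + np.rad2deg(y / EARTH_RADIUS_M)
    return lon, lat
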