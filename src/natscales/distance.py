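"""Geodesic distances on the sphere.

All distances in this package are great-circle (haversine) distances on a
sphere of radius 6371.0088 km (IUGG mean Earth radius), reported in
kilometres. At the regional extents the method targets (city to country),
ellipsoidal corrections are far below the resolution of percentile ranks.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable numpy arrays; returns a float for
    scalar input, an ndarray otherwise.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if d.ndim == 0:
        return float(d)
    return d


def latlon_to_unit_xyz(lat, lon):
    """Map degrees lat/lon to 3-D unit vectors (for exact nearest-neighbour
    queries with a Euclidean KD-tree: chord distance is monotone in arc)."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)],
        axis=-1,
    )
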