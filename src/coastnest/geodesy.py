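"""Great-circle geometry on a spherical Earth.

All distance computations in the pipeline go through :func:`haversine_km`
with a fixed Earth radius of 6371.0 km, so that node matching, habitat
proximity and grid statistics share one metric.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius used for every great-circle computation (km).
EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points in degrees WGS84, in km.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal / coincident points
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


def lonlat_to_unit_vectors(lons, lats) -> np.ndarray:
    lons = np.radians(np.asarray(lons, dtype=float))
    lats = np.radians(np.asarray(lats, dtype=float))
    return np.column_stack(
        [np.cos(lats) * np.cos(lons), np.cos(lats) * np.sin(lons), np.sin(lats)]
    )


def unit_vector_mean(lons, lats) -> tuple[float, float]:
    """Spherical centroid of points: mean of unit vectors, renormalized.

    Robust to longitude wrap-around at the date line, unlike a plain
    arithmetic mean of coordinates.
    """
    v = lonlat_to_unit_vectors(lons, lats).mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate point set: unit vectors cancel exactly")
    v = v / norm
    lat = np.degrees(np.arcsin(np.clip(v[2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[1], v[0]))
    return float(lon), float(lat)


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Forward azimuth from point 1 to point 2, degrees in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    b = np.degrees(np.arctan2(y, x)) % 360.0
    if b.ndim == 0:
        return float(b)
    return b


def destination_point(lon, lat, bearing_deg, dist_km):
    """Point reached travelling ``dist_km`` along ``bearing_deg`` on the sphere."""
    lon1 = np.radians(np.asarray(lon, dtype=float))
    lat1 = np.radians(np.asarray(lat, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    lon2 = (np.degrees(lon2) + 540.0) % 360.0 - 180.0
    lat2 = np.degrees(lat2)
    if lon2.ndim == 0:
        return float(lon2), float(lat2)
    return lon2, lat2


def spherical_polygon_area_km2(lons, lats) -> float:
    """Area of a simple spherical polygon given vertices in degrees.

    Triangulates as a fan around the spherical centroid and sums signed
    solid angles of the triangles (Van Oosterom & Strackee), so slightly
    irregular but convex-ish cells are handled exactly.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.shape[0] >= 2 and lons[0] == lons[-1] and lats[0] == lats[-1]:
        lons, lats = lons[:-1], lats[:-1]
    if lons.shape[0] < 3:
        raise ValueError("polygon needs at least 3 distinct vertices")
    verts = lonlat_to_unit_vectors(lons, lats)
    clon, clat = unit_vector_mean(lons, lats)
    c = lonlat_to_unit_vectors([clon], [clat])[0]
    total = 0.0
    n = verts.shape[0]
    for i in range(n):
        a = verts[i]
        b = verts[(i + 1) % n]
        num = np.dot(c, np.cross(a, b))
        den = 1.0 + np.dot(a, b) + np.dot(b, c) + np.dot(c, a)
        total += 2.0 * np.arctan2(num, den)
    return abs(total) * EARTH_RADIUS_KM**2
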