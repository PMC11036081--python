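"""Spherical geodesy helpers used throughout the pipeline.

All functions work on a sphere of radius 6,371,000 m in WGS84-style
geographic coordinates (decimal degrees, latitude in [-90, 90], longitude
normalised to (-180, 180]).  At the spatial scales the pipeline cares
about (sub-km stationarity thresholds, 5-10 km clustering radii, 22 km
coastal bands) the spherical approximation differs from the ellipsoid by
well under the thresholds involved.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
NM_TO_M = 1852.0


def normalize_lon(lon):
    """Normalise longitudes to the half-open interval (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon - 180.0) % -360.0) + 180.0
    return out if out.ndim else float(out)


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres via the haversine formula.

    Accepts scalars or array-likes (broadcast).  Symmetric, non-negative,
    and numerically stable for small separations (unlike the spherical
    law of cosines).
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dphi = lat2 - lat1
    dlmb = lon2 - lon1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return d if d.ndim else float(d)


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    phi1, lmb1, phi2, lmb2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlmb = lmb2 - lmb1
    y = np.sin(dlmb) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlmb)
    brg = np.degrees(np.arctan2(y, x)) % 360.0
    return brg if brg.ndim else float(brg)


def destination(lat, lon, bearing_deg, distance_m):
    """Destination point given start, initial bearing and great-circle distance."""
    phi1 = np.radians(np.asarray(lat, dtype=float))
    lmb1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    phi2 = np.arcsin(np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta))
    lmb2 = lmb1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * np.sin(phi2))
    la, lo = np.degrees(phi2), normalize_lon(np.degrees(lmb2))
    if np.ndim(la) == 0:
        return float(la), float(lo)
    return la, lo


def gc_interpolate(lat1, lon1, lat2, lon2, fractions):
    """Points along the great circle between two locations.

    ``fractions`` is an array of values in [0, 1]; 0 maps to the start
    point and 1 to the end point.  Coincident endpoints are handled
    (every fraction returns the shared point).
    """
    f = np.asarray(fractions, dtype=float)
    v1 = _unit_vector(lat1, lon1)
    v2 = _unit_vector(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    if omega < 1e-12:
        lats = np.full_like(f, float(lat1))
        lons = np.full_like(f, float(lon1))
        return lats, lons
    s = np.sin(omega)
    v = (np.sin((1.0 - f)[:, None] * omega) * v1[None, :]
         + np.sin(f[:, None] * omega) * v2[None, :]) / s
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    lats = np.degrees(np.arcsin(v[:, 2]))
    lons = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return lats, normalize_lon(lons)


def _unit_vector(lat, lon):
    phi, lmb = np.radians(float(lat)), np.radians(float(lon))
    return np.array([np.cos(phi) * np.cos(lmb), np.cos(phi) * np.sin(lmb), np.sin(phi)])


def ecef_unit(lats, lons):
    """Unit-sphere Cartesian coordinates, one row per point (for KD-trees)."""
    phi = np.radians(np.asarray(lats, dtype=float))
    lmb = np.radians(np.asarray(lons, dtype=float))
    return np.column_stack([np.cos(phi) * np.cos(lmb),
                            np.cos(phi) * np.sin(lmb),
                            np.sin(phi)])


def chord_m(arc_m):
    """Chord length through the sphere for a given surface (arc) distance.

    Used to convert a great-circle search radius into the Euclidean radius
    a KD-tree on unit-sphere coordinates needs (scaled by Earth radius).
    """
    return 2.0 * EARTH_RADIUS_M * np.sin(arc_m / (2.0 * EARTH_RADIUS_M))


def aeqd_project(lat0, lon0, lats, lons):
    """Forward azimuthal equidistant projection centred on (lat0, lon0).

    Returns (x, y) in metres.  Distances from the centre are exactly the
    great-circle distances; this is the projection under which the node
    buffers are defined, so buffer tests and plain great-circle distances
    agree by construction at the centre.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    c = np.asarray(haversine_m(lat0, lon0, lats, lons)) / EARTH_RADIUS_M
    az = np.radians(np.asarray(initial_bearing_deg(lat0, lon0, lats, lons)))
    rho = c * EARTH_RADIUS_M
    x = rho * np.sin(az)
    y = rho * np.cos(az)
    return x, y
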