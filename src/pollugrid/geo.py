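"""Geodesy helpers: great-circle distance and equal-area projections.

Two planar coordinate reference systems are provided:

* :class:`AlbersEqualArea` — spherical Albers equal-area conic, the standard
  choice for continental-scale equal-area gridding (default parallels 25N/47N,
  central meridian 105E suit a China-wide raster).
* :class:`SyntheticPlane` — an exactly invertible local plane used by the
  synthetic generator, so every geodesy code path (forward, inverse,
  haversine) is exercised on data with known planar ground truth.

All planar coordinates are kilometres; all geographic coordinates are WGS84
degrees.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

#: Arc length of one degree on a great circle, km.
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 points (vectorised).

    Symmetric, non-negative and zero iff the points coincide; uses the
    haversine formula on a sphere of radius ``EARTH_RADIUS_KM``.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards tiny negative/overshoot from rounding at antipodes
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _check_lonlat(lon, lat, ids=None):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    bad = ~((lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90))
    if np.any(bad):
        idx = np.nonzero(np.atleast_1d(bad))[0]
        labels = [str(ids[i]) if ids is not None else str(i) for i in idx[:10]]
        raise ValueError(
            f"coordinates outside WGS84 bounds for records: {', '.join(labels)}"
        )
    return lon, lat


class AlbersEqualArea:
    """Spherical Albers equal-area conic projection (km units).

    Equal-area by construction: a 100 km x 100 km planar cell covers the same
    ground area anywhere in the projection, which is the property the raster
    requires.  Parameters default to the usual China configuration.
    """

    def __init__(self, lat1=25.0, lat2=47.0, lon0=105.0, lat0=0.0):
        self.lat1, self.lat2, self.lon0, self.lat0 = lat1, lat2, lon0, lat0
        p1, p2, p0 = np.radians([lat1, lat2, lat0])
        self._n = (np.sin(p1) + np.sin(p2)) / 2.0
        self._C = np.cos(p1) ** 2 + 2.0 * self._n * np.sin(p1)
        self._rho0 = (EARTH_RADIUS_KM
                      * np.sqrt(self._C - 2.0 * self._n * np.sin(p0)) / self._n)

    def forward(self, lon, lat, ids=None):
        lon, lat = _check_lonlat(lon, lat, ids)
        lam = np.radians(lon - self.lon0)
        phi = np.radians(lat)
        rho = EARTH_RADIUS_KM * np.sqrt(self._C - 2.0 * self._n * np.sin(phi)) / self._n
        theta = self._n * lam
        return rho * np.sin(theta), self._rho0 - rho * np.cos(theta)

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, self._rho0 - y)
        theta = np.arctan2(x, self._rho0 - y)
        sinphi = (self._C - (rho * self._n / EARTH_RADIUS_KM) ** 2) / (2.0 * self._n)
        lat = np.degrees(np.arcsin(np.clip(sinphi, -1.0, 1.0)))
        lon = self.lon0 + np.degrees(theta / self._n)
        return lon, lat


class SyntheticPlane:
    """Exactly invertible local plane anchored at (lon0, lat0).

    Northing is proportional to latitude; easting is scaled by cos(lat) at the
    point's own latitude, so the map is a bijection and haversine distances on
    the inverse-mapped coordinates agree with planar distances to first order.
    Used for synthetic panels, where the plane itself is the ground truth.
    """

    def __init__(self, lon0=105.0, lat0=30.0):
        self.lon0, self.lat0 = lon0, lat0

    def forward(self, lon, lat, ids=None):
        lon, lat = _check_lonlat(lon, lat, ids)
        y = (lat - self.lat0) * KM_PER_DEG
        x = (lon - self.lon0) * KM_PER_DEG * np.cos(np.radians(lat))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lat = self.lat0 + y / KM_PER_DEG
        lon = self.lon0 + x / (KM_PER_DEG * np.cos(np.radians(lat)))
        return lon, lat


def project_coordinates(lon, lat, projection, ids=None):
    """Project WGS84 coordinates to planar km with the given projection.

    Raises ``ValueError`` naming the offending record ids when coordinates are
    outside WGS84 bounds.
    """
    return projection.forward(lon, lat, ids=ids)
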