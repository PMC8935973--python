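"""Spherical-earth geographic primitives.

All coordinates are WGS84 decimal degrees ordered (lon, lat). Distances are
great-circle (haversine) on a sphere with the IUGG mean earth radius; at the
city scales this package targets (< 50 km) the difference from an ellipsoidal
(Karney) distance is below 0.3%.
"""

from __future__ import annotations

import numpy as np

#: IUGG mean earth radius in meters.
EARTH_RADIUS_M = 6_371_008.8


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in meters between (lon1, lat1) and (lon2, lat2).

    Accepts scalars or broadcastable arrays of decimal degrees. Symmetric and
    zero iff the points coincide.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection about a center point.

    Distances and bearings from the center are exact on the sphere, so the
    planar arithmetic mean of points near the center agrees with spherical
    averaging to O(d^3 / R^2) — millimeters at city scale. Used for colony
    mean centers.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = np.radians(float(lon0))
        self.lat0 = np.radians(float(lat0))

    def to_xy(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        dlon = lon - self.lon0
        cos_c = np.sin(self.lat0) * np.sin(lat) + np.cos(self.lat0) * np.cos(lat) * np.cos(dlon)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(c), 1.0)
        x = EARTH_RADIUS_M * k * np.cos(lat) * np.sin(dlon)
        y = EARTH_RADIUS_M * k * (
            np.cos(self.lat0) * np.sin(lat) - np.sin(self.lat0) * np.cos(lat) * np.cos(dlon)
        )
        return x, y

    def to_lonlat(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_M
        sin_c, cos_c = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.where(
                rho > 1e-12,
                np.arcsin(cos_c * np.sin(self.lat0) + y * sin_c * np.cos(self.lat0) / np.where(rho > 1e-12, rho, 1.0)),
                self.lat0,
            )
            lon = self.lon0 + np.arctan2(
                x * sin_c, rho * cos_c * np.cos(self.lat0) - y * sin_c * np.sin(self.lat0)
            )
        return np.degrees(lon), np.degrees(lat)


class LocalPlane:
    """Equirectangular tangent-plane projection anchored at a reference point.

    Maps lon/lat to planar meters (x east, y north) with the meridian
    convergence frozen at the anchor latitude. Within a <=50 km extent the
    planar distances and midpoints agree with spherical geodesy to well under
    a meter, which is the regime where colony mean centers are computed.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._coslat0 = np.cos(np.radians(self.lat0))
        self._m_per_deg = EARTH_RADIUS_M * np.pi / 180.0

    def to_xy(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = (lon - self.lon0) * self._m_per_deg * self._coslat0
        y = (lat - self.lat0) * self._m_per_deg
        return x, y

    def to_lonlat(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        lon = self.lon0 + x / (self._m_per_deg * self._coslat0)
        lat = self.lat0 + y / self._m_per_deg
        return lon, lat
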