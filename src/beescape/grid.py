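"""Rectangular study grid in WGS84.

The grid is defined on a local tangent plane anchored at its south-west
origin: rows run north, columns run east, every cell is ``cell_size_m``
square in that plane. Cell membership uses half-open intervals
[west, east) x [south, north) so a point on an interior grid line belongs to
exactly one cell. Cell ids are integers ``row * n_cols + col``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geo import LocalPlane


@dataclass(frozen=True)
class Grid:
    n_rows: int
    n_cols: int
    cell_size_m: float = 2000.0
    origin_lonlat: tuple[float, float] = (-79.6393, 43.581)  # SW corner, Toronto-like
    plane: LocalPlane = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        object.__setattr__(self, "plane", LocalPlane(*self.origin_lonlat))

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    #: sub-micrometer snap so a point that is mathematically on a grid line
    #: lands in its east/north cell even after lon/lat round-tripping
    _EDGE_TOL_M = 1e-6

    def cell_of_xy(self, x, y) -> np.ndarray:
        """Cell id for planar coordinates; -1 for points outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x + self._EDGE_TOL_M) / self.cell_size_m).astype(int)
        row = np.floor((y + self._EDGE_TOL_M) / self.cell_size_m).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row * self.n_cols + col, -1)

    def cell_of_lonlat(self, lon, lat) -> np.ndarray:
        x, y = self.plane.to_xy(lon, lat)
        return self.cell_of_xy(x, y)

    def cell_bounds_xy(self, cell_id: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) in planar meters."""
        row, col = divmod(int(cell_id), self.n_cols)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"cell id {cell_id} outside grid")
        w = col * self.cell_size_m
        s = row * self.cell_size_m
        return w, s, w + self.cell_size_m, s + self.cell_size_m

    def cell_center_lonlat(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        cell_id = np.asarray(cell_id)
        row, col = np.divmod(cell_id, self.n_cols)
        x = (col + 0.5) * self.cell_size_m
        y = (row + 0.5) * self.cell_size_m
        return self.plane.to_lonlat(x, y)

    def to_geojson(self) -> dict:
        """FeatureCollection of cell polygons in WGS84."""
        features = []
        for cid in range(self.n_cells):
            w, s, e, n = self.cell_bounds_xy(cid)
            xs = np.array([w, e, e, w, w])
            ys = np.array([s, s, n, n, s])
            lon, lat = self.plane.to_lonlat(xs, ys)
            ring = [[float(a), float(b)] for a, b in zip(lon, lat)]
            features.append(
                {
                    "type": "Feature",
                    "properties": {"cell_id": cid},
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


def rect_overlap_fraction(cell_bounds, rect_bounds) -> float:
    """Fraction of an axis-aligned cell covered by an axis-aligned rectangle.

    Bounds are (west, south, east, north) in a shared planar frame. This is
    the overlap helper used for synthetic landscapes, where every polygon is
    a rectangle; real-map overlap tables are consumed pre-computed.
    """
    cw, cs, ce, cn = cell_bounds
    rw, rs, re, rn = rect_bounds
    ix = max(0.0, min(ce, re) - max(cw, rw))
    iy = max(0.0, min(cn, rn) - max(cs, rs))
    area = (ce - cw) * (cn - cs)
    if area <= 0:
        raise ValueError("cell has non-positive area")
    return ix * iy / area
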