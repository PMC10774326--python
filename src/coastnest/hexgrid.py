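"""Hexagonal geospatial indexers.

The coastal-region grid is built on ~50-km hexagonal cells. Indexing is
abstracted behind :class:`HexIndexer` so that different hexagonal tilings
can back the same grid-construction code. The default backend tiles a
local equirectangular projection of the longitude/latitude plane with
regular pointy-top hexagons in axial coordinates; an icosahedral H3
backend can be plugged in where the ``h3`` library is available.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod

import numpy as np

from .geodesy import EARTH_RADIUS_KM

SQRT3 = math.sqrt(3.0)

# axial-coordinate offsets of the six neighbours of a pointy-top hexagon
_AXIAL_DIRECTIONS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


class HexIndexer(ABC):
    """Contract every hexagonal backend must satisfy.

    ``cell_of`` is total over the working latitude band, ``neighbors`` is
    symmetric, and cell boundary polygons tile the band without overlap.
    """

    @abstractmethod
    def cell_of(self, lon: float, lat: float):
        "Cell id containing a point (degrees WGS84)."

    @abstractmethod
    def cells_of(self, lons, lats) -> list:
        "Vectorized :meth:`cell_of`."

    @abstractmethod
    def neighbors(self, cell) -> list:
        "Up to six adjacent cell ids."

    @abstractmethod
    def boundary(self, cell) -> np.ndarray:
        "(7, 2) closed ring of (lon, lat) vertices."

    @abstractmethod
    def centroid(self, cell) -> tuple[float, float]:
        "(lon, lat) of the cell center."


class PlanarHexIndexer(HexIndexer):
    """Regular pointy-top hexagons on an equirectangular plane.

    Longitude/latitude are mapped to kilometres with ``x = R cos(lat0) λ``
    and ``y = R φ`` (radians); hexagons of circumradius ``size_km``
    (center to vertex) tile that plane. The default circumradius of 26 km
    gives a vertex-to-vertex diameter of 52 km and a planar cell area of
    (3√3/2)·26² ≈ 1756 km², matching the ~50-km regional resolution the
    grid is designed for. Distortion grows away from ``ref_lat``; the
    backend is intended for latitude bands of a few tens of degrees.
    """

    def __init__(self, size_km: float = 26.0, ref_lat: float = 0.0):
        if size_km <= 0:
            raise ValueError("size_km must be positive")
        self.size_km = float(size_km)
        self.ref_lat = float(ref_lat)
        self._kx = EARTH_RADIUS_KM * math.cos(math.radians(self.ref_lat)) * math.pi / 180.0
        self._ky = EARTH_RADIUS_KM * math.pi / 180.0

    # -- planar <-> geographic ------------------------------------------------
    def _to_xy(self, lons, lats):
        return np.asarray(lons, float) * self._kx, np.asarray(lats, float) * self._ky

    def _to_lonlat(self, x, y):
        return np.asarray(x, float) / self._kx, np.asarray(y, float) / self._ky

    # -- axial hex math -------------------------------------------------------
    def _axial_of_xy(self, x, y):
        s = self.size_km
        q = (SQRT3 / 3.0 * x - y / 3.0) / s
        r = (2.0 / 3.0 * y) / s
        return _cube_round(q, r)

    def _center_xy(self, cell):
        q, r = cell
        s = self.size_km
        x = s * (SQRT3 * q + SQRT3 / 2.0 * r)
        y = s * (1.5 * r)
        return x, y

    # -- HexIndexer interface -------------------------------------------------
    # cell ids are strings "q,r" (axial coordinates), so they behave as
    # plain labels in tables, GeoJSON properties and file names
    @staticmethod
    def _axial(cell: str) -> tuple[int, int]:
        q, r = cell.split(",")
        return int(q), int(r)

    def cell_of(self, lon, lat):
        q, r = self._axial_of_xy(*self._to_xy(lon, lat))
        return f"{int(q)},{int(r)}"

    def cells_of(self, lons, lats):
        x, y = self._to_xy(lons, lats)
        q, r = self._axial_of_xy(x, y)
        return [f"{qi},{ri}" for qi, ri in
                zip(np.atleast_1d(q).astype(int), np.atleast_1d(r).astype(int))]

    def neighbors(self, cell):
        q, r = self._axial(cell)
        return [f"{q + dq},{r + dr}" for dq, dr in _AXIAL_DIRECTIONS]

    def boundary(self, cell):
        cx, cy = self._center_xy(self._axial(cell))
        # pointy-top vertices at 30°, 90°, ..., 330°
        ang = np.radians(30.0 + 60.0 * np.arange(6))
        xs = cx + self.size_km * np.cos(ang)
        ys = cy + self.size_km * np.sin(ang)
        xs = np.append(xs, xs[0])
        ys = np.append(ys, ys[0])
        lon, lat = self._to_lonlat(xs, ys)
        return np.column_stack([lon, lat])

    def centroid(self, cell):
        lon, lat = self._to_lonlat(*self._center_xy(self._axial(cell)))
        return float(lon), float(lat)


def _cube_round(q, r):
    """Round fractional axial coordinates to the containing hexagon."""
    q = np.asarray(q, float)
    r = np.asarray(r, float)
    s = -q - r
    rq, rr, rs = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(rq - q), np.abs(rr - r), np.abs(rs - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    rq = np.where(fix_q, -rr - rs, rq)
    rr = np.where(fix_r, -rq - rs, rr)
    if rq.ndim == 0:
        return int(rq), int(rr)
    return rq.astype(int), rr.astype(int)


class H3Indexer(HexIndexer):
    """Icosahedral hierarchical backend delegating to the ``h3`` library.

    Optional: construction raises ``ImportError`` when ``h3`` is not
    installed. Resolution 4 (~1770 km² cells) matches the planar
    backend's scale.
    """

    def __init__(self, resolution: int = 4):
        try:
            import h3  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the 'h3' package is required for the icosahedral backend; "
                "install it or use PlanarHexIndexer"
            ) from exc
        self._h3 = h3
        self.resolution = int(resolution)

    def cell_of(self, lon, lat):  # pragma: no cover - optional dependency
        return self._h3.latlng_to_cell(lat, lon, self.resolution)

    def cells_of(self, lons, lats):  # pragma: no cover
        return [self.cell_of(lo, la) for lo, la in zip(np.atleast_1d(lons), np.atleast_1d(lats))]

    def neighbors(self, cell):  # pragma: no cover
        return [c for c in self._h3.grid_ring(cell, 1)]

    def boundary(self, cell):  # pragma: no cover
        ring = [(lon, lat) for lat, lon in self._h3.cell_to_boundary(cell)]
        ring.append(ring[0])
        return np.asarray(ring)

    def centroid(self, cell):  # pragma: no cover
        lat, lon = self._h3.cell_to_latlng(cell)
        return float(lon), float(lat)


def get_indexer(backend: str = "planar", **kwargs) -> HexIndexer:
    """Factory used by the CLI: ``planar`` (built-in) or ``h3`` (optional)."""
    if backend == "planar":
        return PlanarHexIndexer(**kwargs)
    if backend == "h3":
        return H3Indexer(**kwargs)
    raise ValueError(f"unknown hex backend {backend!r}; choose 'planar' or 'h3'")
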