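"""Construction of the hexagonal coastal-region grid.

Shoreline transects (~1-km spacing) are overlaid on a hexagonal tiling;
every cell covering at least one transect becomes a candidate coastal
cell. Candidates representing only a few kilometres of coast are then
removed greedily (fewest transects first) when they also lack coastal
neighbors, under a no-gap constraint: a removal that would leave a
transect of a contiguous stretch farther than 100 km from every
surviving cell is skipped. Transects of removed cells are relinked to
the nearest surviving cell within 100 km, or dropped. Each surviving
cell gets a coastline centroid (CLC): the spherical mean of its linked
transect positions, the anchor for all node matching downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodesy import haversine_km, spherical_polygon_area_km2, unit_vector_mean
from .hexgrid import HexIndexer
from .registry import SPECIES

logger = logging.getLogger(__name__)

TRANSECT_COLUMNS = ("transect_id", "lon", "lat", "shoreline_angle",
                    "beta_ns", "beta_bs", "z_max", "p_built")


@dataclass
class GridConfig:
    """Grid refinement parameters.

    ``min_transects``/``min_neighbors``: a candidate cell is removed when
    it has fewer transects than the former AND fewer coastal neighbors
    than the latter. ``max_link_km``: inclusive relink radius (a transect
    farther than this from every surviving cell is dropped).
    ``snap_km``: radius for attaching offshore nesting sites to the
    nearest CLC. Latitude bounds default to the band holding all known
    nesting grounds plus a buffer.
    """

    min_transects: int = 5
    min_neighbors: int = 1
    max_link_km: float = 100.0
    lat_bounds: tuple = (-39.0, 48.0)
    snap_km: float = 25.0


@dataclass
class Coastgon:
    """One hexagonal coastal region: linked transects, CLC, nesting state."""

    cell_id: object
    transect_ids: list
    clc_lon: float
    clc_lat: float
    nesting: dict = field(default_factory=lambda: {sp: 0 for sp in SPECIES})


@dataclass
class CoastgonGrid:
    cells: dict                      # cell_id -> Coastgon
    indexer: HexIndexer
    config: GridConfig
    dropped_transects: list
    n_input_transects: int

    def clc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": list(self.cells),
                "lon": [c.clc_lon for c in self.cells.values()],
                "lat": [c.clc_lat for c in self.cells.values()],
            }
        )

    def nesting_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {sp: [c.nesting.get(sp, 0) for c in self.cells.values()] for sp in SPECIES},
            index=pd.Index(list(self.cells), name="cell_id"),
        )

    def links_frame(self) -> pd.DataFrame:
        rows = [(tid, cid) for cid, c in self.cells.items() for tid in c.transect_ids]
        return pd.DataFrame(rows, columns=["transect_id", "cell_id"])


def _clc_of(transects: pd.DataFrame, ids: list) -> tuple[float, float]:
    sub = transects.loc[ids]
    return unit_vector_mean(sub["lon"].to_numpy(), sub["lat"].to_numpy())


def build_grid(transects: pd.DataFrame, indexer: HexIndexer,
               config: GridConfig | None = None) -> CoastgonGrid:
    """Overlay, refine and link: transect table -> coastal-region grid.

    The transect table must carry at least transect_id, lon, lat. See the
    module docstring for the refinement semantics.
    """
    config = config or GridConfig()
    if len(transects) == 0:
        raise ValueError("empty transect set")
    lo, hi = config.lat_bounds
    inband = transects[(transects["lat"] >= lo) & (transects["lat"] <= hi)]
    if len(inband) == 0:
        raise ValueError(f"no transects within latitude bounds {config.lat_bounds}")
    inband = inband.set_index("transect_id", drop=False)

    cell_ids = indexer.cells_of(inband["lon"].to_numpy(), inband["lat"].to_numpy())
    members: dict = {}
    for tid, cid in zip(inband["transect_id"], cell_ids):
        members.setdefault(cid, []).append(tid)

    clc = {cid: _clc_of(inband, tids) for cid, tids in members.items()}
    dropped: list = []

    def neighbor_count(cid):
        return sum(1 for nb in indexer.neighbors(cid) if nb in members)

    def nearest_survivor(tid, exclude):
        t = inband.loc[tid]
        best, best_d = None, np.inf
        for cid, (clon, clat) in clc.items():
            if cid == exclude:
                continue
            d = haversine_km(t["lon"], t["lat"], clon, clat)
            if d < best_d:
                best, best_d = cid, d
        return best, best_d

    # greedy refinement, fewest transects first; repeat until a full pass
    # removes nothing
    removed_any = True
    while removed_any:
        removed_any = False
        candidates = sorted(
            (cid for cid in members
             if len(members[cid]) < config.min_transects
             and neighbor_count(cid) < config.min_neighbors),
            key=lambda cid: (len(members[cid]), str(cid)),
        )
        for cid in candidates:
            if cid not in members or len(members) == 1:
                continue
            targets = [nearest_survivor(tid, cid) for tid in members[cid]]
            stranded = [d > config.max_link_km for _, d in targets]
            if any(stranded) and neighbor_count(cid) > 0:
                # no-gap constraint: removal would orphan part of a
                # contiguous stretch -> keep the cell
                continue
            for tid, (tgt, d) in zip(members[cid], targets):
                if d <= config.max_link_km:
                    members[tgt].append(tid)
                    clc[tgt] = _clc_of(inband, members[tgt])
                else:
                    dropped.append(tid)
                    logger.warning("transect %s dropped: %.0f km from every surviving cell", tid, d)
            del members[cid]
            del clc[cid]
            removed_any = True

    cells = {}
    for cid in sorted(members, key=str):
        lon, lat = _clc_of(inband, members[cid])
        cells[cid] = Coastgon(cell_id=cid, transect_ids=sorted(members[cid]),
                              clc_lon=lon, clc_lat=lat)
    return CoastgonGrid(cells=cells, indexer=indexer, config=config,
                        dropped_transects=sorted(dropped),
                        n_input_transects=len(transects))


def assign_nesting(grid: CoastgonGrid, sites: pd.DataFrame,
                   snap_km: float | None = None) -> CoastgonGrid:
    """Flag per-species nesting on the grid (binary, in place; returns grid).

    A cell's flag becomes 1 when any site of that species falls inside
    its boundary, regardless of how many sites or turtles that is. Sites
    in no coastal cell are attached to the nearest CLC within ``snap_km``
    (default from the grid config), otherwise logged and ignored.
    """
    snap = grid.config.snap_km if snap_km is None else snap_km
    unknown = set(sites["species"]) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species code(s) {sorted(unknown)}; valid: {SPECIES}")
    if len(sites) == 0:
        return grid
    clcs = grid.clc_frame()
    for _, site in sites.iterrows():
        cid = grid.indexer.cell_of(site["lon"], site["lat"])
        if cid not in grid.cells:
            d = haversine_km(site["lon"], site["lat"],
                             clcs["lon"].to_numpy(), clcs["lat"].to_numpy())
            j = int(np.argmin(d))
            if d[j] <= snap:
                cid = clcs["cell_id"].iloc[j]
            else:
                logger.warning(
                    "nesting site (%.3f, %.3f, %s) ignored: %.0f km from nearest CLC (snap %.0f km)",
                    site["lon"], site["lat"], site["species"], d[j], snap)
                continue
        grid.cells[cid].nesting[site["species"]] = 1
    return grid


def grid_stats(grid: CoastgonGrid) -> dict:
    """Cell-geometry and linkage summary of a built grid.

    Areas are spherical polygon areas (km^2); the diameter is the
    maximum vertex-to-vertex great-circle distance (km).
    """
    areas, diams = [], []
    for cid in grid.cells:
        ring = grid.indexer.boundary(cid)
        areas.append(spherical_polygon_area_km2(ring[:, 0], ring[:, 1]))
        v = ring[:-1]
        dmax = 0.0
        for i in range(len(v)):
            d = haversine_km(v[i, 0], v[i, 1], v[:, 0], v[:, 1])
            dmax = max(dmax, float(np.max(d)))
        diams.append(dmax)
    counts = np.array([len(c.transect_ids) for c in grid.cells.values()])
    areas = np.asarray(areas)
    diams = np.asarray(diams)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return {
            "n_cells": len(grid.cells),
            "n_transects_linked": int(counts.sum()),
            "n_transects_dropped": len(grid.dropped_transects),
            "area_mean_km2": float(areas.mean()),
            "area_sd_km2": float(areas.std(ddof=1)) if len(areas) > 1 else 0.0,
            "diameter_mean_km": float(diams.mean()),
            "diameter_sd_km": float(diams.std(ddof=1)) if len(diams) > 1 else 0.0,
            "transects_per_cell_min": int(counts.min()),
            "transects_per_cell_median": float(np.median(counts)),
            "transects_per_cell_max": int(counts.max()),
        }
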