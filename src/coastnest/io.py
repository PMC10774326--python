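"""Plain-text readers and writers: GeoJSON for vector data, CSV for tables.

GeoJSON is written directly as JSON (RFC 7946 FeatureCollections) and
read through shapely, keeping every artifact diffable text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .registry import SPECIES


# cell ids are plain strings across all backends; these shims keep the
# file layer explicit about where ids cross an IO boundary
def cell_id_to_str(cid) -> str:
    return str(cid)


def cell_id_from_str(s) -> str:
    return str(s)


def _feature(geometry, properties) -> dict:
    return {"type": "Feature", "geometry": mapping(geometry), "properties": properties}


def write_geojson(features: list, path, extra: dict | None = None) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_geojson(path) -> dict:
    return json.loads(Path(path).read_text())


# -- grid -------------------------------------------------------------------
def write_grid_geojson(grid, path) -> None:
    """One polygon feature per coastal cell with CLC, linkage and nesting
    flags in the properties."""
    features = []
    for cid, cg in grid.cells.items():
        ring = grid.indexer.boundary(cid)
        props = {
            "cell_id": cell_id_to_str(cid),
            "clc_lon": cg.clc_lon,
            "clc_lat": cg.clc_lat,
            "n_transects": len(cg.transect_ids),
            **{f"nesting_{sp}": int(cg.nesting.get(sp, 0)) for sp in SPECIES},
        }
        features.append(_feature(Polygon(ring), props))
    write_geojson(features, path, extra={"backend": type(grid.indexer).__name__})


def write_links_csv(grid, path) -> None:
    links = grid.links_frame()
    links["cell_id"] = links["cell_id"].map(cell_id_to_str)
    links.to_csv(path, index=False)


# -- habitats ---------------------------------------------------------------
def write_habitats_geojson(habitats: dict, path) -> None:
    features = [_feature(poly, {"variable": var})
                for var, polys in sorted(habitats.items()) for poly in polys]
    write_geojson(features, path)


def read_habitats_geojson(path) -> dict:
    doc = read_geojson(path)
    out: dict = {}
    for feat in doc["features"]:
        out.setdefault(feat["properties"]["variable"], []).append(shape(feat["geometry"]))
    return out


# -- regions ----------------------------------------------------------------
def read_regions_geojson(path) -> dict:
    """name -> polygon; the demo file shipped with the package holds
    approximate, non-authoritative rectangles."""
    doc = read_geojson(path)
    return {feat["properties"]["name"]: shape(feat["geometry"]) for feat in doc["features"]}


def write_regions_geojson(regions: dict, path) -> None:
    write_geojson([_feature(poly, {"name": name}) for name, poly in regions.items()], path)


def demo_regions_path() -> Path:
    return Path(__file__).parent / "data" / "regions_synthetic_demo.geojson"


def load_demo_regions() -> dict:
    return read_regions_geojson(demo_regions_path())


# -- tables -----------------------------------------------------------------
def write_indicator_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index = [cell_id_to_str(c) for c in out.index]
    out.index.name = "cell_id"
    out.to_csv(path)


def read_indicator_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="cell_id")
    table.index = [cell_id_from_str(s) for s in table.index]
    return table


def write_suitability_geojson(grid, categories: pd.DataFrame, path) -> None:
    """Per-cell polygon features carrying the O/S/U category per species."""
    features = []
    for cid, cg in grid.cells.items():
        ring = grid.indexer.boundary(cid)
        props = {"cell_id": cell_id_to_str(cid)}
        if cid in categories.index:
            for sp in categories.columns:
                props[f"category_{sp}"] = categories.loc[cid, sp]
        features.append(_feature(Polygon(ring), props))
    write_geojson(features, path)


def jsonable(obj):
    """Recursively convert numpy scalars/arrays and pandas objects for json.dump."""
    if isinstance(obj, dict):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, pd.Series):
        return {str(k): jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
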