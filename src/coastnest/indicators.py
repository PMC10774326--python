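"""Derivation of the 22 regional coastal indicators.

Each coastal cell is summarized by a fixed vector of indicators spanning
hydrodynamic, atmospheric, geophysical, habitat and human processes
(:data:`coastnest.registry.INDICATOR_COLUMNS`). Time-series indicators
are computed per environmental node first and then averaged over the
``k`` nodes nearest to the cell's coastline centroid (CLC), with ``k``
depending on the source dataset class and a hard 100-km matching radius;
cells with no node in range get NaN for that class. Geophysical and
human indicators are computed from the shoreline transects linked to the
cell, and habitat indicators are great-circle distances from the CLC to
the nearest habitat polygon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point
from shapely.prepared import prep

from .geodesy import haversine_km
from .registry import (
    CLASS_INDICATORS,
    DATASET_CLASSES,
    DEFAULT_MATCH_K,
    INDICATOR_COLUMNS,
    MATCH_MAX_KM,
    TIMESERIES_INDICATORS,
    VARIABLES,
)

#: length (hours) of one tidal cycle window used for the mean tidal range
#: (two semidiurnal cycles: 24 h 50 min)
DEFAULT_TIDE_WINDOW_HOURS = 24.0 + 50.0 / 60.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class MatchRule:
    """k-nearest-node matching rule per dataset class (max distance 100 km)."""

    k: dict = field(default_factory=lambda: dict(DEFAULT_MATCH_K))
    max_km: float = MATCH_MAX_KM


@dataclass
class NodeSeriesSet:
    """Time series of one dataset class on a set of geolocated nodes.

    ``series[variable]`` is an ``(n_nodes, n_times)`` array aligned with
    the rows of ``nodes`` (columns: node_id, lon, lat).
    """

    dataset_class: str
    nodes: pd.DataFrame
    times_h: np.ndarray
    series: dict
    units: dict

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.times_h = t
        for var, arr in self.series.items():
            if var not in VARIABLES:
                raise ValueError(
                    f"unknown variable {var!r}; valid names: {sorted(VARIABLES)}"
                )
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(self.nodes), t.size):
                raise ValueError(f"series {var!r} shape {arr.shape} does not match nodes/times")
            self.series[var] = arr

    @property
    def dt_hours(self) -> float:
        return float(self.times_h[1] - self.times_h[0]) if self.times_h.size > 1 else np.nan

    # -- plain-text IO (long format) ----------------------------------------
    def to_csv(self, nodes_path, series_path) -> None:
        self.nodes.to_csv(nodes_path, index=False)
        frames = []
        for var, arr in sorted(self.series.items()):
            long = pd.DataFrame(
                {
                    "time_h": np.tile(self.times_h, len(self.nodes)),
                    "node_id": np.repeat(self.nodes["node_id"].to_numpy(), self.times_h.size),
                    "variable": var,
                    "value": arr.reshape(-1),
                    "units": self.units[var],
                }
            )
            frames.append(long)
        pd.concat(frames, ignore_index=True).to_csv(series_path, index=False)

    @classmethod
    def from_csv(cls, dataset_class, nodes_path, series_path) -> "NodeSeriesSet":
        nodes = pd.read_csv(nodes_path)
        long = pd.read_csv(series_path)
        times = np.sort(long["time_h"].unique())
        series, units = {}, {}
        order = {nid: i for i, nid in enumerate(nodes["node_id"])}
        for var, grp in long.groupby("variable"):
            u = grp["units"].unique()
            if len(u) > 1:
                raise ValueError(f"unit mismatch for variable {var!r}: {sorted(u)}")
            units[var] = u[0]
            arr = np.full((len(nodes), times.size), np.nan)
            tidx = {t: j for j, t in enumerate(times)}
            i = grp["node_id"].map(order).to_numpy()
            j = grp["time_h"].map(tidx).to_numpy()
            arr[i, j] = grp["value"].to_numpy()
            series[var] = arr
        return cls(dataset_class, nodes, times, series, units)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------
def series_stats(values, which: str) -> float:
    """Median, 95th percentile, or sample standard deviation of a series.

    Percentiles use linear interpolation between closest order
    statistics; std uses the n-1 divisor. NaNs are ignored; an empty or
    all-NaN series yields NaN.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    if which == "median":
        return float(np.median(values))
    if which == "p95":
        return float(np.percentile(values, 95.0, method="linear"))
    if which == "std":
        if values.size < 2:
            return float("nan")
        return float(np.std(values, ddof=1))
    raise ValueError(f"unknown statistic {which!r}")


def compute_madm(values) -> float:
    """Median absolute deviation from the median, normalized by the median.

    A robust, scale-free variability measure: MADm = 1 means half the
    samples deviate from the median by more than the median itself.
    Undefined (NaN, with a warning) when the median is zero.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan")
    med = float(np.median(values))
    if med == 0.0:
        warnings.warn("MADm undefined for zero median", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.median(np.abs(values - med)) / med)


def circular_std_deg(angles_deg) -> float:
    """Circular standard deviation of angles in degrees.

    Uses the resultant-length definition, so {359, 1} has dispersion ~1
    degree rather than ~179. The plain (linear) alternative is available
    via :func:`series_stats` for convention matching.
    """
    angles = np.asarray(angles_deg, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        return float("nan")
    return float(sps.circstd(angles, high=360.0, low=0.0))


# ---------------------------------------------------------------------------
# node matching
# ---------------------------------------------------------------------------
def match_nodes(clc, nodes: pd.DataFrame, k: int, max_km: float = MATCH_MAX_KM) -> list:
    """Ids of the <=k nearest nodes within ``max_km`` of the CLC.

    Sorted by distance; exact distance ties broken by ascending node id.
    Returns an empty list when no node is in range (NaN downstream).
    """
    lon, lat = clc
    d = haversine_km(lon, lat, nodes["lon"].to_numpy(), nodes["lat"].to_numpy())
    d = np.atleast_1d(d)
    ids = nodes["node_id"].to_numpy()
    order = np.lexsort((ids, d))
    picked = [int(ids[i]) if np.issubdtype(ids.dtype, np.integer) else ids[i]
              for i in order if d[i] <= max_km][:k]
    return picked


def _matched_indices(clcs: np.ndarray, nodes: pd.DataFrame, k: int, max_km: float):
    """Vectorized matching: list of node-row index arrays, one per CLC."""
    nlon = nodes["lon"].to_numpy()
    nlat = nodes["lat"].to_numpy()
    ids = nodes["node_id"].to_numpy()
    out = []
    for lon, lat in clcs:
        d = np.atleast_1d(haversine_km(lon, lat, nlon, nlat))
        order = np.lexsort((ids, d))
        order = order[d[order] <= max_km][:k]
        out.append(order)
    return out


# ---------------------------------------------------------------------------
# per-node statistics and node-averaged indicators
# ---------------------------------------------------------------------------
def tidal_range_per_node(values: np.ndarray, dt_hours: float,
                         window_hours: float = DEFAULT_TIDE_WINDOW_HOURS) -> np.ndarray:
    """Mean tidal range per node: mean over successive windows of (max - min).

    ``values`` is (n_nodes, n_times); windows of one tidal-cycle length
    (default 24 h 50 min); a trailing partial window is discarded.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    steps = int(round(window_hours / dt_hours))
    if steps < 2:
        raise ValueError("tide window must span at least 2 samples")
    n_win = values.shape[1] // steps
    if n_win == 0:
        return np.full(values.shape[0], np.nan)
    v = values[:, : n_win * steps].reshape(values.shape[0], n_win, steps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        rng_ = np.nanmax(v, axis=2) - np.nanmin(v, axis=2)
        return np.nanmean(rng_, axis=1)


def _node_stats(values: np.ndarray, stat: str, dt_hours: float, tide_window_hours: float) -> np.ndarray:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if stat == "tidal_range":
        return tidal_range_per_node(values, dt_hours, tide_window_hours)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if stat == "median":
            return np.nanmedian(values, axis=1)
        if stat == "p95":
            return np.nanpercentile(values, 95.0, axis=1, method="linear")
        if stat == "std":
            return np.nanstd(values, ddof=1, axis=1)
    raise ValueError(f"unknown statistic {stat!r}")


def derive_node_indicators(clcs: pd.DataFrame, node_sets: dict,
                           rule: MatchRule | None = None,
                           tide_window_hours: float = DEFAULT_TIDE_WINDOW_HOURS):
    """Node-averaged time-series indicators for each cell.

    ``clcs`` has columns cell_id, lon, lat. For every indicator the
    statistic is computed per matched node and then arithmetically
    averaged over nodes (NaN-only nodes are skipped); cells with no
    matched node in a dataset class get NaN for that class's indicators.
    Returns (DataFrame indexed by cell_id, provenance dict).
    """
    rule = rule or MatchRule()
    out = pd.DataFrame(index=clcs["cell_id"])
    provenance = {cid: {} for cid in clcs["cell_id"]}
    pts = clcs[["lon", "lat"]].to_numpy()
    for cls in DATASET_CLASSES:
        nset = node_sets.get(cls)
        if nset is None:
            for name in CLASS_INDICATORS[cls]:
                out[name] = np.nan
            continue
        matches = _matched_indices(pts, nset.nodes, rule.k[cls], rule.max_km)
        ids = nset.nodes["node_id"].to_numpy()
        for cid, m in zip(clcs["cell_id"], matches):
            provenance[cid][cls] = [ids[i].item() if hasattr(ids[i], "item") else ids[i] for i in m]
        for name, var, stat in TIMESERIES_INDICATORS:
            if VARIABLES[var][0] != cls:
                continue
            if var not in nset.series:
                out[name] = np.nan
                continue
            per_node = _node_stats(nset.series[var], stat, nset.dt_hours, tide_window_hours)
            vals = np.full(len(matches), np.nan)
            for i, m in enumerate(matches):
                if len(m):
                    sel = per_node[m]
                    if np.isfinite(sel).any():
                        vals[i] = np.nanmean(sel)
            out[name] = vals
    return out, provenance


def current_proximity(clcs: pd.DataFrame, current_set: NodeSeriesSet | None,
                      threshold: float = 0.3) -> pd.Series:
    """Distance (km) from each CLC to the nearest node whose median current
    speed is >= ``threshold`` m/s (inclusive); NaN when no node qualifies."""
    idx = clcs["cell_id"]
    if current_set is None or "current" not in current_set.series:
        return pd.Series(np.nan, index=idx, name="D_c_03")
    med = _node_stats(current_set.series["current"], "median", current_set.dt_hours,
                      DEFAULT_TIDE_WINDOW_HOURS)
    qual = np.isfinite(med) & (med >= threshold)
    if not qual.any():
        return pd.Series(np.nan, index=idx, name="D_c_03")
    qlon = current_set.nodes["lon"].to_numpy()[qual]
    qlat = current_set.nodes["lat"].to_numpy()[qual]
    vals = [float(np.min(haversine_km(lon, lat, qlon, qlat))) for lon, lat in clcs[["lon", "lat"]].to_numpy()]
    return pd.Series(vals, index=idx, name="D_c_03")


# ---------------------------------------------------------------------------
# habitat proximity
# ---------------------------------------------------------------------------
def densify_ring(coords: np.ndarray, max_seg_km: float = 1.0) -> np.ndarray:
    """Insert vertices so no ring edge exceeds ``max_seg_km`` (great-circle)."""
    coords = np.asarray(coords, dtype=float)
    out = []
    for i in range(len(coords) - 1):
        a, b = coords[i], coords[i + 1]
        d = haversine_km(a[0], a[1], b[0], b[1])
        n = max(1, int(np.ceil(d / max_seg_km)))
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        # chord interpolation in lon/lat; adequate for the ~km segments used here
        out.append(np.column_stack([a[0] + (b[0] - a[0]) * t, a[1] + (b[1] - a[1]) * t]))
    out.append(coords[-1:])
    return np.vstack(out)


def habitat_distance(clc, polygons, max_seg_km: float = 1.0) -> float:
    """Min great-circle distance (km) from the CLC to any polygon boundary,
    with edges densified to <= ``max_seg_km``; 0 when the CLC lies inside."""
    if not polygons:
        return float("nan")
    lon, lat = clc
    p = Point(lon, lat)
    best = np.inf
    for poly in polygons:
        if poly.contains(p) or poly.touches(p):
            return 0.0
        rings = [np.asarray(poly.exterior.coords)] + [np.asarray(r.coords) for r in poly.interiors]
        for ring in rings:
            dense = densify_ring(ring, max_seg_km)
            d = haversine_km(lon, lat, dense[:, 0], dense[:, 1])
            best = min(best, float(np.min(d)))
    return best


def habitat_distances(clcs: pd.DataFrame, habitats: dict, max_seg_km: float = 1.0) -> pd.DataFrame:
    """D_cor and D_sgr for every cell. ``habitats`` maps variable
    ('coral'/'seagrass') to a list of shapely polygons."""
    out = pd.DataFrame(index=clcs["cell_id"])
    for var, col in (("coral", "D_cor"), ("seagrass", "D_sgr")):
        polys = habitats.get(var, [])
        if not polys:
            out[col] = np.nan
            continue
        dense_all = np.vstack([
            densify_ring(np.asarray(r.coords), max_seg_km)
            for poly in polys
            for r in [poly.exterior, *poly.interiors]
        ])
        prepared = [prep(poly) for poly in polys]
        vals = np.empty(len(clcs))
        for i, (lon, lat) in enumerate(clcs[["lon", "lat"]].to_numpy()):
            p = Point(lon, lat)
            if any(pr.intersects(p) for pr in prepared):
                vals[i] = 0.0
            else:
                vals[i] = float(np.min(haversine_km(lon, lat, dense_all[:, 0], dense_all[:, 1])))
        out[col] = vals
    return out


# ---------------------------------------------------------------------------
# geophysical / human indicators from transects
# ---------------------------------------------------------------------------
def derive_geophysical(transects: pd.DataFrame, circular_angles: bool = True) -> dict:
    """Geophysical and human indicators over a cell's linked transects.

    phi_std is the circular standard deviation of shoreline angles by
    default (the linear convention is kept behind ``circular_angles=False``
    for dataset matching); slopes and elevation use medians, elevation
    dispersion the sample std, and built fraction the mean.
    """
    ang = transects["shoreline_angle"].to_numpy(dtype=float)
    phi = circular_std_deg(ang) if circular_angles else series_stats(ang, "std")
    return {
        "phi_std": phi,
        "beta_ns_med": series_stats(transects["beta_ns"], "median"),
        "beta_bs_med": series_stats(transects["beta_bs"], "median"),
        "z_max_med": series_stats(transects["z_max"], "median"),
        "z_max_std": series_stats(transects["z_max"], "std"),
        "p_built": float(np.nanmean(transects["p_built"].to_numpy(dtype=float))),
    }


# ---------------------------------------------------------------------------
# full table assembly
# ---------------------------------------------------------------------------
def derive_indicators(grid, transects: pd.DataFrame, node_sets: dict,
                      habitats: dict | None = None,
                      rule: MatchRule | None = None,
                      tide_window_hours: float = DEFAULT_TIDE_WINDOW_HOURS,
                      circular_angles: bool = True):
    """Assemble the full 22-indicator table for a built grid.

    Returns ``(table, provenance)`` where ``table`` is indexed by cell id
    with columns :data:`INDICATOR_COLUMNS` plus per-species nesting flags
    when the grid carries them.
    """
    habitats = habitats or {}
    clcs = grid.clc_frame()
    ts_table, provenance = derive_node_indicators(clcs, node_sets, rule, tide_window_hours)
    dc03 = current_proximity(clcs, node_sets.get("oras5"))
    hab = habitat_distances(clcs, habitats)

    tx = transects.set_index("transect_id")
    geo_rows = {}
    for cid, cg in grid.cells.items():
        geo_rows[cid] = derive_geophysical(tx.loc[list(cg.transect_ids)], circular_angles)
    geo = pd.DataFrame.from_dict(geo_rows, orient="index")
    geo.index.name = "cell_id"

    table = pd.concat([ts_table, dc03, geo, hab], axis=1)
    table = table[list(INDICATOR_COLUMNS)]
    for sp, flags in grid.nesting_frame().items():
        table[f"nesting_{sp}"] = flags
    return table, provenance
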