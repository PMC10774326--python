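"""Synthetic coastal datasets with planted statistical structure.

No public generator exists for the four input classes the pipeline
consumes (shoreline transects, environmental node time series, habitat
polygons, nesting sites), so this module fabricates all of them around a
parametric coastline, with known structure that downstream stages must
recover:

* transects at fixed alongshore spacing carrying geophysical attributes;
* environmental nodes on coarse, seaward-offset lattices with AR(1)
  time series around smooth spatial means (tide as a sinusoid);
* circular coral/seagrass habitat patches;
* nesting presence drawn from a logistic model on percentile-scaled
  indicators, so the indicator-nesting relationships are planted and
  recoverable by construction.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit
from shapely.geometry import Polygon

from . import clustering
from .geodesy import destination_point, haversine_km, initial_bearing_deg
from .indicators import NodeSeriesSet
from .registry import HABITAT_VARIABLES, INDICATOR_COLUMNS, SPECIES, VARIABLES

#: default node spacing (km) per dataset class, mimicking source resolutions
DEFAULT_NODE_SPACING = {"era5_wave": 55.0, "era5_atmos": 28.0, "oras5": 28.0, "gtsm": 40.0}
#: default seaward offset (km) of each class's node lattice
DEFAULT_NODE_OFFSET = {"era5_wave": 20.0, "era5_atmos": 15.0, "oras5": 25.0, "gtsm": 10.0}


# ---------------------------------------------------------------------------
# field specifications
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SpatialMean:
    """Spatial mean of a variable as a function of alongshore fraction u in [0, 1].

    kinds: 'constant' (value), 'linear' (start..end), 'gaussian'
    (base + amp * exp(-(u - center)^2 / (2 width^2))).
    """

    kind: str = "constant"
    value: float = 0.0
    start: float = 0.0
    end: float = 0.0
    base: float = 0.0
    amp: float = 0.0
    center: float = 0.5
    width: float = 0.1

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        if self.kind == "constant":
            out = np.full_like(u, self.value)
        elif self.kind == "linear":
            out = self.start + (self.end - self.start) * u
        elif self.kind == "gaussian":
            out = self.base + self.amp * np.exp(-((u - self.center) ** 2) / (2.0 * self.width**2))
        else:
            raise ValueError(f"unknown spatial mean kind {self.kind!r}")
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnvFieldSpec:
    """AR(1) time series around a spatial mean: x_t = mu + phi (x_{t-1} - mu) + eps.

    For the tide variable ``mean`` is the sinusoid *amplitude* field and
    ``period_hours`` sets the (semidiurnal, by default) period.
    """

    variable: str
    mean: SpatialMean
    ar1_phi: float = 0.0
    noise_sd: float = 0.0
    period_hours: float = 12.42

    def __post_init__(self):
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; valid: {sorted(VARIABLES)}")
        if not abs(self.ar1_phi) < 1:
            raise ValueError("ar1_phi must satisfy |phi| < 1 (stationarity)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class TransectFieldSpec:
    """Geophysical/human attribute per transect: spatial mean + iid noise, clipped."""

    mean: SpatialMean
    noise_sd: float = 0.0
    clip: tuple = (None, None)


@dataclass(frozen=True)
class HabitatPatchSpec:
    variable: str
    lon: float
    lat: float
    radius_km: float

    def __post_init__(self):
        if self.variable not in HABITAT_VARIABLES:
            raise ValueError(f"habitat variable must be one of {HABITAT_VARIABLES}")


@dataclass(frozen=True)
class NestingModelSpec:
    """Planted logistic presence model on percentile-scaled indicators.

    p = expit(beta0 + sum_j beta_j z_j); presence is a seeded Bernoulli
    draw unless ``deterministic_threshold`` is set, in which case
    presence = (p >= threshold) exactly.
    """

    species: str = "CM"
    beta0: float = 0.0
    betas: dict = field(default_factory=dict)
    deterministic_threshold: float | None = None

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; valid: {SPECIES}")
        bad = set(self.betas) - set(INDICATOR_COLUMNS)
        if bad:
            raise ValueError(f"coefficients reference unknown indicators: {sorted(bad)}")


@dataclass
class SynthConfig:
    """Full specification of one synthetic study area."""

    seed: int = 0
    control_points: np.ndarray = None  # (n, 2) lon/lat of the coastline
    transect_spacing_km: float = 1.0
    n_timesteps: int = 1440
    dt_hours: float = 1.0
    env_fields: list = field(default_factory=list)
    transect_fields: dict = field(default_factory=dict)
    habitat_patches: list = field(default_factory=list)
    nesting: NestingModelSpec = field(default_factory=NestingModelSpec)
    node_spacing_km: dict = field(default_factory=lambda: dict(DEFAULT_NODE_SPACING))
    node_offset_km: dict = field(default_factory=lambda: dict(DEFAULT_NODE_OFFSET))
    resolution_km: float = 0.25  # densification step for the coastline curve

    def __post_init__(self):
        if self.transect_spacing_km <= 0:
            raise ValueError("transect_spacing_km must be positive")
        if self.n_timesteps < 2:
            raise ValueError("n_timesteps must be >= 2")
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.ndim != 2 or self.control_points.shape[0] < 2:
            raise ValueError("coastline needs at least 2 control points")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# coastline and transects
# ---------------------------------------------------------------------------
def _dense_curve(config: SynthConfig):
    """Densified polyline (lon, lat, cumulative arc length km) of the coastline."""
    pts = config.control_points
    lons, lats = [pts[0, 0]], [pts[0, 1]]
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        d = haversine_km(a[0], a[1], b[0], b[1])
        n = max(1, int(np.ceil(d / config.resolution_km)))
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        lons.extend(a[0] + (b[0] - a[0]) * t)
        lats.extend(a[1] + (b[1] - a[1]) * t)
    lons = np.asarray(lons)
    lats = np.asarray(lats)
    seg = haversine_km(lons[:-1], lats[:-1], lons[1:], lats[1:])
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("degenerate coastline: zero total length")
    return lons, lats, s


def _points_at(lons, lats, s, targets):
    lon = np.interp(targets, s, lons)
    lat = np.interp(targets, s, lats)
    return lon, lat


def _bearings_at(lons, lats, s, targets, ds: float = 0.05):
    t2 = np.minimum(targets + ds, s[-1])
    t1 = t2 - ds
    lon1, lat1 = _points_at(lons, lats, s, t1)
    lon2, lat2 = _points_at(lons, lats, s, t2)
    return np.atleast_1d(initial_bearing_deg(lon1, lat1, lon2, lat2))


def coastline_length_km(config: SynthConfig) -> float:
    return float(_dense_curve(config)[2][-1])


def point_along(config: SynthConfig, u: float) -> tuple[float, float]:
    """(lon, lat) at alongshore fraction u of the coastline."""
    lons, lats, s = _dense_curve(config)
    lon, lat = _points_at(lons, lats, s, u * s[-1])
    return float(lon), float(lat)


def generate_coastline(config: SynthConfig) -> pd.DataFrame:
    """Transect table: evenly spaced shore points with attributes.

    Transects sit at multiples of the spacing from the curve start,
    n = floor(L / spacing) + 1 of them, so both endpoints carry a
    transect whenever the length is a multiple of the spacing. The
    shoreline angle is the local tangent bearing (degrees in [0, 360)).
    """
    lons, lats, s = _dense_curve(config)
    length = s[-1]
    if length < 10 * config.transect_spacing_km:
        raise ValueError("coastline length must be at least 10 x transect spacing")
    n = int(np.floor(length / config.transect_spacing_km)) + 1
    targets = np.arange(n) * config.transect_spacing_km
    lon, lat = _points_at(lons, lats, s, targets)
    angle = _bearings_at(lons, lats, s, targets)
    u = targets / length
    rng = config.rng(0)
    df = pd.DataFrame(
        {
            "transect_id": np.arange(n),
            "lon": lon,
            "lat": lat,
            "shoreline_angle": angle % 360.0,
            "u": u,
        }
    )
    for name in ("beta_ns", "beta_bs", "z_max", "p_built"):
        spec = config.transect_fields.get(name)
        if spec is None:
            df[name] = 0.0
            continue
        vals = np.asarray(spec.mean(u), dtype=float) + rng.normal(0.0, spec.noise_sd, n)
        lo, hi = spec.clip
        df[name] = np.clip(vals, lo, hi)
    return df


# ---------------------------------------------------------------------------
# environmental nodes and time series
# ---------------------------------------------------------------------------
def generate_env_nodes(config: SynthConfig) -> dict:
    """Node lattices per dataset class, offset seaward of the coastline.

    Nodes follow the coast at the class spacing, shifted 90 degrees left
    of the travel direction by the class offset, so the k-nearest-node
    matching is exercised nontrivially (some cells see fewer than k
    nodes in range, some none).
    """
    lons, lats, s = _dense_curve(config)
    length = s[-1]
    out = {}
    for cls, spacing in config.node_spacing_km.items():
        targets = np.arange(spacing / 2.0, length, spacing)
        lon, lat = _points_at(lons, lats, s, targets)
        brg = _bearings_at(lons, lats, s, targets)
        off = config.node_offset_km.get(cls, 0.0)
        nlon, nlat = destination_point(lon, lat, (brg - 90.0) % 360.0, off)
        out[cls] = pd.DataFrame(
            {
                "node_id": np.arange(len(targets)),
                "lon": np.atleast_1d(nlon),
                "lat": np.atleast_1d(nlat),
                "u": targets / length,
            }
        )
    return out


def _ar1(rng, mu, phi, sd, n_t, burn: int = 100):
    """(n_nodes, n_t) AR(1) around per-node means mu, stationary via burn-in."""
    n_nodes = mu.shape[0]
    eps = rng.normal(0.0, sd, (n_nodes, n_t + burn)) if sd > 0 else np.zeros((n_nodes, n_t + burn))
    dev = lfilter([1.0], [1.0, -phi], eps, axis=1)[:, burn:]
    return mu[:, None] + dev


def generate_env_timeseries(config: SynthConfig) -> dict:
    """Dataset-class -> :class:`NodeSeriesSet` with all configured variables."""
    nodes = generate_env_nodes(config)
    rng = config.rng(1)
    times = np.arange(config.n_timesteps) * config.dt_hours
    sets: dict = {}
    by_class: dict = {}
    for spec in config.env_fields:
        by_class.setdefault(VARIABLES[spec.variable][0], []).append(spec)
    for cls, specs in sorted(by_class.items()):
        ndf = nodes[cls]
        series, units = {}, {}
        for spec in sorted(specs, key=lambda sp: sp.variable):
            mu = np.asarray(spec.mean(ndf["u"].to_numpy()), dtype=float)
            if spec.variable == "tide":
                # mu is the amplitude field; signal is a sinusoid + noise
                base = mu[:, None] * np.sin(2.0 * np.pi * times / spec.period_hours)[None, :]
                noise = (rng.normal(0.0, spec.noise_sd, base.shape)
                         if spec.noise_sd > 0 else 0.0)
                series["tide"] = base + noise
            else:
                series[spec.variable] = _ar1(rng, mu, spec.ar1_phi, spec.noise_sd,
                                             config.n_timesteps)
            units[spec.variable] = VARIABLES[spec.variable][1]
        sets[cls] = NodeSeriesSet(cls, ndf, times, series, units)
    return sets


# ---------------------------------------------------------------------------
# habitats
# ---------------------------------------------------------------------------
def _circle_polygon(lon, lat, radius_km, n_vertices: int = 64) -> Polygon:
    brg = np.linspace(0.0, 360.0, n_vertices, endpoint=False)
    plon, plat = destination_point(lon, lat, brg, radius_km)
    return Polygon(np.column_stack([plon, plat]))


def generate_habitats(config: SynthConfig) -> dict:
    """variable -> list of shapely polygons (circular patches)."""
    out = {v: [] for v in HABITAT_VARIABLES}
    for patch in config.habitat_patches:
        out[patch.variable].append(_circle_polygon(patch.lon, patch.lat, patch.radius_km))
    return out


# ---------------------------------------------------------------------------
# nesting
# ---------------------------------------------------------------------------
def nesting_probabilities(config: SynthConfig, table: pd.DataFrame) -> pd.Series:
    """Planted presence probability per cell from the logistic model.

    Indicators are percentile-scaled on the table itself; cells with NaN
    in any planted indicator get probability 0 (they cannot nest).
    """
    spec = config.nesting
    missing = [c for c in spec.betas if c not in table.columns]
    if missing:
        raise ValueError(f"nesting model references indicators absent from table: {missing}")
    if not spec.betas:
        p = np.full(len(table), expit(spec.beta0))
        return pd.Series(p, index=table.index, name="p_nest")
    cols = sorted(spec.betas)
    params = clustering.fit_scaler(table, cols)
    z = clustering.transform(params, table[cols])
    eta = spec.beta0 + sum(spec.betas[c] * z[c] for c in cols)
    p = expit(eta.to_numpy(dtype=float))
    p[~np.isfinite(p)] = 0.0
    bad = ~np.isfinite(z.to_numpy(dtype=float)).all(axis=1)
    p[bad] = 0.0
    return pd.Series(p, index=table.index, name="p_nest")


def generate_nesting(config: SynthConfig, table: pd.DataFrame,
                     clcs: pd.DataFrame) -> pd.DataFrame:
    """Nesting-site points (lon, lat, species) from the planted model.

    One site at the cell's CLC per presence. Bernoulli draws are seeded;
    with ``deterministic_threshold`` set, presences are exactly the cells
    whose probability reaches the threshold.
    """
    p = nesting_probabilities(config, table)
    spec = config.nesting
    if spec.deterministic_threshold is not None:
        present = p.to_numpy() >= spec.deterministic_threshold
    else:
        rng = config.rng(2)
        present = rng.random(len(p)) < p.to_numpy()
    pos = clcs.set_index("cell_id").loc[p.index[present]]
    return pd.DataFrame(
        {"lon": pos["lon"].to_numpy(), "lat": pos["lat"].to_numpy(),
         "species": spec.species}
    )


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------
def default_control_points(n: int = 361, lon_span: float = 105.0) -> np.ndarray:
    """A long, meandering low-latitude coastline (~16,600 km)."""
    u = np.linspace(0.0, 1.0, n)
    lon = lon_span * u - 30.0
    lat = 8.0 * np.sin(2.0 * np.pi * 2.5 * u) + 3.0 * np.sin(2.0 * np.pi * 5.5 * u + 1.0)
    return np.column_stack([lon, lat])


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The canonical synthetic study area (~450 coastal cells).

    A ~16,600-km meandering coastline with 1-km transects; sea surface
    temperature rises linearly along the coast (16 -> 30 degC) while the
    tidal amplitude peaks in a bulge (0.15 -> ~1.25 m) inside the warm
    half, so both planted drivers shape the boundary of the suitable
    set. Nesting is planted on h_tide (negative) and SST_med (positive)
    with steep coefficients, so presence probabilities are near 0 or 1
    for almost every cell and the planted high-probability set is well
    defined; the intercept puts prevalence near 15%.
    """
    cfg = SynthConfig(
        seed=seed,
        control_points=default_control_points(),
        env_fields=[
            EnvFieldSpec("hs", SpatialMean("constant", value=1.5), ar1_phi=0.8, noise_sd=0.5),
            EnvFieldSpec("tp", SpatialMean("constant", value=8.0), ar1_phi=0.8, noise_sd=1.5),
            EnvFieldSpec("surge", SpatialMean("constant", value=0.08), ar1_phi=0.9, noise_sd=0.05),
            EnvFieldSpec("tide", SpatialMean("gaussian", base=0.15, amp=1.1, center=0.5, width=0.3),
                         noise_sd=0.02),
            EnvFieldSpec("current", SpatialMean("gaussian", base=0.15, amp=0.35, center=0.75, width=0.1),
                         ar1_phi=0.8, noise_sd=0.05),
            EnvFieldSpec("u10", SpatialMean("constant", value=6.0), ar1_phi=0.7, noise_sd=2.0),
            EnvFieldSpec("sst", SpatialMean("linear", start=16.0, end=30.0), ar1_phi=0.9, noise_sd=0.6),
            EnvFieldSpec("precip", SpatialMean("constant", value=1200.0), ar1_phi=0.3, noise_sd=250.0),
        ],
        transect_fields={
            "beta_ns": TransectFieldSpec(SpatialMean("constant", value=0.02), 0.008, (1e-4, None)),
            "beta_bs": TransectFieldSpec(SpatialMean("constant", value=0.06), 0.02, (1e-4, None)),
            "z_max": TransectFieldSpec(SpatialMean("constant", value=8.0), 3.0, (0.0, None)),
            "p_built": TransectFieldSpec(SpatialMean("constant", value=12.0), 10.0, (0.0, 100.0)),
        },
        nesting=NestingModelSpec(species="CM", beta0=-6.0,
                                 betas={"h_tide": -12.0, "SST_med": 12.0}),
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    if not cfg.habitat_patches:
        # circular habitat patches anchored to the coastline, slightly offshore
        patches = []
        for var, u, radius in (("coral", 0.2, 40.0), ("coral", 0.55, 60.0), ("coral", 0.85, 35.0),
                               ("seagrass", 0.1, 50.0), ("seagrass", 0.45, 40.0), ("seagrass", 0.7, 55.0)):
            lon, lat = point_along(cfg, u)
            patches.append(HabitatPatchSpec(var, lon, lat, radius))
        cfg.habitat_patches = patches
    return cfg
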