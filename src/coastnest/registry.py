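"""Shared registry of environmental variables, dataset classes and indicators.

The pipeline derives 22 regional indicators per coastal cell, grouped in
five categories (hydrodynamic, atmospheric, geophysical, habitat, human).
Time-series indicators come from four classes of gridded sources, each
with its own node-matching multiplicity ``k`` reflecting the source
resolution relative to the ~50-km cells.
"""

from __future__ import annotations

#: Sea turtle species codes: loggerhead, green, hawksbill, leatherback, olive ridley.
SPECIES = ("CC", "CM", "EI", "DC", "LO")

#: environmental variable -> (dataset class, units)
VARIABLES = {
    "hs": ("era5_wave", "m"),        # significant wave height
    "tp": ("era5_wave", "s"),        # peak wave period
    "surge": ("gtsm", "m"),          # storm surge level
    "tide": ("gtsm", "m"),           # tide level
    "current": ("oras5", "m/s"),     # near-surface current speed
    "u10": ("era5_atmos", "m/s"),    # 10-m wind speed
    "sst": ("era5_atmos", "degC"),   # sea surface temperature
    "precip": ("era5_atmos", "mm/y"),  # total annual precipitation
}

DATASET_CLASSES = ("era5_wave", "era5_atmos", "oras5", "gtsm")

#: default k of the k-nearest-node matching rule, per dataset class
DEFAULT_MATCH_K = {"era5_wave": 1, "era5_atmos": 2, "oras5": 2, "gtsm": 3}

#: maximum node-matching distance (km); beyond it an indicator is NaN
MATCH_MAX_KM = 100.0

#: (indicator, variable, statistic) for the node-averaged time-series indicators
TIMESERIES_INDICATORS = (
    ("H_s_med", "hs", "median"),
    ("H_s_p95", "hs", "p95"),
    ("T_p_med", "tp", "median"),
    ("T_p_p95", "tp", "p95"),
    ("T_p_std", "tp", "std"),
    ("h_S_med", "surge", "median"),
    ("h_S_p95", "surge", "p95"),
    ("h_tide", "tide", "tidal_range"),
    ("u_c_med", "current", "median"),
    ("U10_med", "u10", "median"),
    ("U10_p95", "u10", "p95"),
    ("SST_med", "sst", "median"),
    ("P_med", "precip", "median"),
)

#: geophysical indicators computed from linked shoreline transects
#: (the human indicator p_built is transect-derived too; it closes the vector)
TRANSECT_INDICATORS = ("phi_std", "beta_ns_med", "beta_bs_med", "z_max_med", "z_max_std")

#: habitat / proximity indicators computed from the coastline centroid
DISTANCE_INDICATORS = ("D_c_03", "D_cor", "D_sgr")

#: the full indicator vector, in canonical column order (ASCII symbol names)
INDICATOR_COLUMNS = tuple(
    [name for name, _, _ in TIMESERIES_INDICATORS[:9]]
    + ["D_c_03"]
    + [name for name, _, _ in TIMESERIES_INDICATORS[9:]]
    + list(TRANSECT_INDICATORS)
    + ["D_cor", "D_sgr", "p_built"]
)

HABITAT_VARIABLES = ("coral", "seagrass")

#: which indicators belong to which dataset class (node-averaged ones only)
CLASS_INDICATORS = {
    cls: tuple(n for n, v, _ in TIMESERIES_INDICATORS if VARIABLES[v][0] == cls)
    for cls in DATASET_CLASSES
}


def _check_columns():
    assert len(INDICATOR_COLUMNS) == 22, INDICATOR_COLUMNS
    assert len(set(INDICATOR_COLUMNS)) == 22


_check_columns()
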