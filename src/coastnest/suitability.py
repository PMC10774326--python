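"""Cluster statistics, suitability classification and regional summaries.

Each SOM cluster is summarized by its share of nesting cells and its
indicator medians; Spearman's rho between the two across clusters
captures monotone indicator-nesting relationships (|rho| < 0.1
insignificant, 0.1-0.3 weak, >= 0.3 significant). Cells are then
classified per species as observed nesting (O), potentially suitable (S:
non-nesting members of clusters with at least 10% nesting cells) or
unsuitable (U); the O set approximates the realized niche, O union S the
fundamental niche. Regional summaries report P_O (percent observed) and
P_S (percent observed or suitable) per region and species, with
cross-species means, and two-sample Kolmogorov-Smirnov tests with
Benjamini-Hochberg adjustment compare indicator distributions across the
three categories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point
from shapely.prepared import prep
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterAssignment

logger = logging.getLogger(__name__)

CATEGORIES = ("O", "S", "U")
RHO_WEAK = 0.1
RHO_SIGNIFICANT = 0.3


# ---------------------------------------------------------------------------
# cluster statistics and correlation
# ---------------------------------------------------------------------------
def cluster_stats(assignment: ClusterAssignment, table: pd.DataFrame,
                  species: str, indicators: list) -> pd.DataFrame:
    """Per-cluster member count, nesting share and indicator medians.

    Indexed by neuron index over all k clusters; empty clusters have
    n = 0 and NaN statistics (they are excluded from correlation).
    """
    label_col = f"nesting_{species}"
    missing = assignment.bmu.index.difference(table.index)
    if len(missing):
        raise ValueError(f"assignment ids missing from table: {list(missing)[:5]}...")
    sub = table.loc[assignment.bmu.index]
    rows = []
    members = assignment.members()
    for j in range(assignment.k):
        ids = members[j]
        if not ids:
            rows.append({"cluster": j, "n": 0, "n_nesting": 0, "pct_nesting": np.nan,
                         **{c: np.nan for c in indicators}})
            continue
        grp = sub.loc[ids]
        nest = int(grp[label_col].sum())
        med = grp[indicators].median()
        rows.append({"cluster": j, "n": len(ids), "n_nesting": nest,
                     "pct_nesting": 100.0 * nest / len(ids), **med.to_dict()})
    return pd.DataFrame(rows).set_index("cluster")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    NaN (with a warning) for constant input, where ranks carry no
    information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman's rho undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


def rho_category(rho: float) -> str:
    if not np.isfinite(rho):
        return "insignificant"
    a = abs(rho)
    if a >= RHO_SIGNIFICANT:
        return "significant"
    if a >= RHO_WEAK:
        return "weak"
    return "insignificant"


@dataclass
class CorrelationResult:
    species: str
    rho: pd.Series                  # indicator -> Spearman rho
    category: pd.Series             # indicator -> insignificant/weak/significant
    p_n: float                      # % of non-empty clusters containing nesting
    n_clusters_used: int


def correlate_clusters(stats: pd.DataFrame, indicators: list,
                       species: str = "") -> CorrelationResult:
    """Spearman rho between cluster indicator medians and nesting share,
    over non-empty clusters only."""
    used = stats[stats["n"] > 0]
    if len(used) < 3:
        raise ValueError(f"need >= 3 non-empty clusters, got {len(used)}")
    rhos, cats = {}, {}
    for ind in indicators:
        rho = spearman_rho(used[ind].to_numpy(), used["pct_nesting"].to_numpy())
        rhos[ind] = rho
        cats[ind] = rho_category(rho)
    p_n = 100.0 * float((used["n_nesting"] > 0).mean())
    return CorrelationResult(species=species, rho=pd.Series(rhos),
                             category=pd.Series(cats), p_n=p_n,
                             n_clusters_used=len(used))


# ---------------------------------------------------------------------------
# suitability classification
# ---------------------------------------------------------------------------
def classify_suitability(assignment: ClusterAssignment, table: pd.DataFrame,
                         species: str, threshold_pct: float = 10.0,
                         indicators: list | None = None) -> pd.DataFrame:
    """Per-cell category for one species.

    O for nesting cells; S for non-nesting members of clusters whose
    nesting share reaches ``threshold_pct`` (inclusive); U otherwise.
    Cells absent from the assignment (unclustered, e.g. NaN indicators)
    are U with ``unclustered = True``. Returns a frame indexed like the
    table with columns ``category`` and ``unclustered``.
    """
    label_col = f"nesting_{species}"
    stats = cluster_stats(assignment, table, species, indicators or [])
    suitable_clusters = set(stats.index[(stats["n"] > 0)
                                        & (stats["pct_nesting"] >= threshold_pct)])
    cat = pd.Series("U", index=table.index, name="category")
    unclustered = pd.Series(True, index=table.index, name="unclustered")
    unclustered.loc[assignment.bmu.index] = False
    in_suitable = assignment.bmu[assignment.bmu.isin(suitable_clusters)].index
    cat.loc[in_suitable] = "S"
    cat.loc[table.index[table[label_col] == 1]] = "O"
    return pd.DataFrame({"category": cat, "unclustered": unclustered})


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------
def assign_regions(clcs: pd.DataFrame, regions: dict) -> pd.Series:
    """Region name per cell by CLC point-in-polygon; NaN outside all regions.

    ``regions`` maps name -> shapely polygon; overlapping polygons are an
    error (a cell must belong to at most one region).
    """
    names = list(regions)
    offenders = [
        (a, b)
        for i, a in enumerate(names)
        for b in names[i + 1:]
        if regions[a].intersects(regions[b]) and regions[a].intersection(regions[b]).area > 1e-12
    ]
    if offenders:
        raise ValueError(f"overlapping region polygons: {offenders}")
    prepared = {name: prep(poly) for name, poly in regions.items()}
    out = pd.Series(np.nan, index=clcs["cell_id"], dtype=object, name="region")
    for cid, lon, lat in clcs[["cell_id", "lon", "lat"]].itertuples(index=False):
        pt = Point(lon, lat)
        for name, pr in prepared.items():
            if pr.intersects(pt):
                out.loc[cid] = name
                break
    return out


def summarize_regions(categories: pd.DataFrame, region_of: pd.Series | None = None,
                      include_global: bool = True) -> pd.DataFrame:
    """P_O / P_S per region and species, with cross-species means.

    ``categories`` has one column per species holding 'O'/'S'/'U' per
    cell. A species enters a region's cross-species mean only when it
    has observed nesting there (regions where a species does not nest at
    all are excluded from its mean, matching how absent species are
    reported). Percentages are full precision; see :func:`round_half_even`
    for presentation rounding.
    """
    species_cols = list(categories.columns)
    groups: list[tuple[str, pd.Index]] = []
    if region_of is not None:
        region_of = region_of.reindex(categories.index)
        for name in pd.unique(region_of.dropna()):
            groups.append((name, categories.index[region_of == name]))
    if include_global or region_of is None:
        groups.append(("Global", categories.index))
    rows = []
    for name, idx in groups:
        sub = categories.loc[idx]
        row: dict = {"region": name, "n_cells": len(idx)}
        po_vals, ps_vals = [], []
        for sp in species_cols:
            n = len(sub)
            n_o = int((sub[sp] == "O").sum())
            n_s = int((sub[sp] == "S").sum())
            if n == 0 or n_o == 0:
                row[f"P_O_{sp}"] = np.nan
                row[f"P_S_{sp}"] = np.nan
                continue
            po = 100.0 * n_o / n
            ps = 100.0 * (n_o + n_s) / n
            row[f"P_O_{sp}"] = po
            row[f"P_S_{sp}"] = ps
            po_vals.append(po)
            ps_vals.append(ps)
        row["P_O_mean"] = float(np.mean(po_vals)) if po_vals else np.nan
        row["P_S_mean"] = float(np.mean(ps_vals)) if ps_vals else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def cross_species_means(per_species: pd.DataFrame) -> pd.DataFrame:
    """Row-wise cross-species means of a P_O/P_S table.

    Expects columns ``P_O_<sp>`` / ``P_S_<sp>``; NaN cells (species with
    no data in the region) are skipped, matching the dashes of a
    published-style summary table.
    """
    po_cols = [c for c in per_species.columns if c.startswith("P_O_") and c != "P_O_mean"]
    ps_cols = [c for c in per_species.columns if c.startswith("P_S_") and c != "P_S_mean"]
    out = per_species.copy()
    out["P_O_mean"] = per_species[po_cols].mean(axis=1, skipna=True)
    out["P_S_mean"] = per_species[ps_cols].mean(axis=1, skipna=True)
    return out


def expansion_ratio(summary: pd.DataFrame, region: str = "Global") -> float:
    """Ratio of the global cross-species mean P_S to mean P_O: how much
    larger the fundamental niche is than the realized one."""
    row = summary.loc[region]
    return float(row["P_S_mean"] / row["P_O_mean"])


def round_half_even(x, decimals: int = 1):
    """Presentation rounding (banker's) used for reported percentages."""
    return np.round(np.asarray(x, dtype=float) + 0.0, decimals)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov comparisons
# ---------------------------------------------------------------------------
PAIRS = (("O", "S"), ("O", "U"), ("S", "U"))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def ks_compare(categories: pd.Series, table: pd.DataFrame, indicators: list,
               alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample KS tests per indicator across category pairs.

    ``categories`` holds 'O'/'S'/'U' per cell for one species. P-values
    are exact when the smaller sample has <= 25 members, asymptotic
    otherwise, and are BH-adjusted within each indicator across its
    (up to three) pair comparisons; pairs with a category smaller than 2
    are skipped with a warning.
    """
    rows = []
    for ind in indicators:
        vals = {c: table.loc[categories.index[categories == c], ind].dropna().to_numpy()
                for c in CATEGORIES}
        raw = []
        for a, b in PAIRS:
            if len(vals[a]) < 2 or len(vals[b]) < 2:
                warnings.warn(
                    f"KS pair {a}|{b} skipped for {ind}: category with < 2 members",
                    RuntimeWarning, stacklevel=2)
                raw.append((a, b, np.nan, np.nan, len(vals[a]), len(vals[b])))
                continue
            method = "exact" if min(len(vals[a]), len(vals[b])) <= 25 else "asymp"
            res = sps.ks_2samp(vals[a], vals[b], method=method)
            raw.append((a, b, float(res.statistic), float(res.pvalue),
                        len(vals[a]), len(vals[b])))
        tested = [r for r in raw if np.isfinite(r[3])]
        adj = bh_adjust([r[3] for r in tested]) if tested else []
        adj_iter = iter(adj)
        for a, b, d, p, na, nb in raw:
            p_adj = float(next(adj_iter)) if np.isfinite(p) else np.nan
            rows.append({"indicator": ind, "pair": f"{a}|{b}", "D": d, "p": p,
                         "p_adj": p_adj, "significant": bool(p_adj < alpha) if np.isfinite(p_adj) else False,
                         "n_a": na, "n_b": nb})
    return pd.DataFrame(rows)
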