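"""End-to-end orchestration: synthetic study generation and full analysis.

``run_study`` fabricates a complete synthetic study area (coastline,
grid, indicators, planted nesting); ``analyze_study`` runs the method on
it (random-forest screening, indicator selection, percentile scaling,
MaxDiss-initialized SOM, cluster correlation, suitability classification
and regional summaries). Both are deterministic given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering, importance, suitability, synth
from .coastgrid import CoastgonGrid, GridConfig, assign_nesting, build_grid
from .hexgrid import HexIndexer, PlanarHexIndexer
from .indicators import derive_indicators
from .registry import SPECIES


@dataclass
class StudyData:
    """A generated study area with ground truth attached."""

    config: synth.SynthConfig
    transects: pd.DataFrame
    node_sets: dict
    habitats: dict
    grid: CoastgonGrid
    table: pd.DataFrame              # indicators + nesting flags, indexed by cell
    provenance: dict
    probabilities: pd.Series         # planted presence probability per cell
    sites: pd.DataFrame              # generated nesting-site points


def run_study(config: synth.SynthConfig | None = None, seed: int = 0,
              indexer: HexIndexer | None = None,
              grid_config: GridConfig | None = None) -> StudyData:
    """Generate the synthetic datasets and derive the indicator table."""
    config = config or synth.default_config(seed)
    indexer = indexer or PlanarHexIndexer()
    transects = synth.generate_coastline(config)
    node_sets = synth.generate_env_timeseries(config)
    habitats = synth.generate_habitats(config)
    grid = build_grid(transects, indexer, grid_config)
    table, provenance = derive_indicators(grid, transects, node_sets, habitats)
    probabilities = synth.nesting_probabilities(config, table)
    sites = synth.generate_nesting(config, table, grid.clc_frame())
    assign_nesting(grid, sites)
    for sp, flags in grid.nesting_frame().items():
        table[f"nesting_{sp}"] = flags
    return StudyData(config=config, transects=transects, node_sets=node_sets,
                     habitats=habitats, grid=grid, table=table,
                     provenance=provenance, probabilities=probabilities, sites=sites)


@dataclass
class AnalysisResult:
    species: str
    importance: importance.ImportanceResult
    scores: importance.PerformanceScores
    selected: list
    scaler: clustering.ScalerParams
    model: clustering.SOMModel
    assignment: clustering.ClusterAssignment
    stats: pd.DataFrame
    correlation: suitability.CorrelationResult
    categories: pd.DataFrame         # per-cell category + unclustered flag
    summary: pd.DataFrame
    n_unclustered: int = 0
    ks: pd.DataFrame = field(default_factory=pd.DataFrame)


def analyze_study(table: pd.DataFrame, species: str = "CM",
                  rf_config: importance.RFConfig | None = None,
                  som_config: clustering.SOMConfig | None = None,
                  n_select: int = 6, threshold_pct: float = 10.0,
                  region_of: pd.Series | None = None,
                  override: list | None = None,
                  run_ks: bool = False) -> AnalysisResult:
    """Run the full method on an indicator table with nesting flags."""
    rf_config = rf_config or importance.RFConfig()
    som_config = som_config or clustering.SOMConfig(seed=rf_config.seed)

    imp, scores = importance.fit_importance(table, species, rf_config)
    corr = importance.indicator_correlations(table)
    selected = importance.select_indicators(imp, corr, n=n_select, override=override)

    complete = table[selected].dropna()
    scaler = clustering.fit_scaler(complete, selected)
    scaled = clustering.transform(scaler, complete)
    data = scaled.to_numpy(dtype=float)
    k = min(som_config.k, len(data))
    if k < som_config.k:
        raise ValueError(
            f"only {len(data)} complete rows for a k={som_config.k} map; "
            "reduce the lattice or supply more cells")
    init = data[clustering.maxdiss_select(data, som_config.k)]
    model = clustering.train_som(data, init, som_config)
    assignment = clustering.assign_clusters(model, scaled)

    stats = suitability.cluster_stats(assignment, table, species, selected)
    correlation = suitability.correlate_clusters(stats, selected, species)
    categories = suitability.classify_suitability(assignment, table, species,
                                                  threshold_pct, selected)
    cat_frame = pd.DataFrame({species: categories["category"]})
    summary = suitability.summarize_regions(cat_frame, region_of)
    ks = (suitability.ks_compare(categories["category"], table, selected)
          if run_ks else pd.DataFrame())
    return AnalysisResult(species=species, importance=imp, scores=scores,
                          selected=selected, scaler=scaler, model=model,
                          assignment=assignment, stats=stats,
                          correlation=correlation, categories=categories,
                          summary=summary,
                          n_unclustered=int(categories["unclustered"].sum()),
                          ks=ks)


def recovery_jaccard(result: AnalysisResult, probabilities: pd.Series,
                     p_cut: float = 0.5) -> float:
    """Overlap (Jaccard) between the recovered O union S set and the
    planted high-probability set {p > p_cut}."""
    cat = result.categories["category"]
    recovered = set(cat.index[cat.isin(["O", "S"])])
    truth = set(probabilities.index[probabilities > p_cut])
    union = recovered | truth
    if not union:
        return float("nan")
    return len(recovered & truth) / len(union)


def analyze_all_species(table: pd.DataFrame, **kwargs) -> dict:
    """Per-species analyses for every species with at least one nesting cell."""
    out = {}
    for sp in SPECIES:
        col = f"nesting_{sp}"
        if col in table.columns and table[col].sum() > 0:
            out[sp] = analyze_study(table, species=sp, **kwargs)
    return out
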