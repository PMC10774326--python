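# coastnest

Regional coastal indicators, hexagonal coastline gridding, SOM
clustering and nesting-suitability mapping for sea turtle habitats.

## The problem

Sea turtles nest on sandy beaches whose suitability is shaped by
regional coastal conditions — water levels, waves, temperature, nearby
foraging habitat, human pressure. Local beach studies rarely transfer
between regions, and global analyses need a single spatial unit that can
absorb heterogeneous data sources (kilometre-scale shoreline transects,
half-degree reanalysis grids, habitat polygons, point records of nesting
sites). `coastnest` implements, as a tested and reusable pipeline, a
regional-scale workflow for explaining where the five globally
distributed species (loggerhead *Caretta caretta* CC, green *Chelonia
mydas* CM, hawksbill *Eretmochelys imbricata* EI, leatherback
*Dermochelys coriacea* DC, olive ridley *Lepidochelys olivacea* LO)
nest, and for mapping where else they plausibly could:

1. **Coastal-region grid** — shoreline transects at ~1-km spacing are
   aggregated into ~50-km hexagonal cells ("coastgons"), each treated as
   a spatially homogeneous coastal region with a binary per-species
   nesting state and a representative coastline centroid (CLC).
2. **22 regional indicators** per cell, spanning hydrodynamic
   (H_s,med/p95, T_p,med/p95/std, h_S,med/p95, h_tide, u_c,med, D_c,0.3),
   atmospheric (U10,med/p95, SST_med, P_med), geophysical (phi_std,
   beta_ns,med, beta_bs,med, z_max,med/std), habitat (D_cor, D_sgr) and
   human (p_built) processes. Time-series indicators are computed per
   environmental node, then averaged over the k nearest nodes within
   100 km of the CLC (k per source class; great-circle distances,
   R = 6371 km); cells with no node in range get NaN.
3. **Random-forest screening** — one classifier per species separates
   nesting from non-nesting cells; normalized feature importances rank
   the indicators, a 4-fold cross-validation checks rank stability, and
   a greedy collinearity-aware rule selects six indicators per species.
4. **SOM clustering** — selected indicators are scaled so min -> 0 and
   the 99.9th percentile -> 1 (outliers exceed 1 instead of compressing
   the bulk), k = 169 neurons on a 13x13 lattice are initialized with a
   maximum-dissimilarity subset and trained online. Spearman's rho
   between cluster indicator medians and the percentage of nesting cells
   per cluster quantifies monotone indicator-nesting relationships
   (|rho| >= 0.3 significant, 0.1-0.3 weak, < 0.1 insignificant).
5. **Suitability maps** — each cell is observed nesting (O), potentially
   suitable (S: non-nesting member of a cluster with >= 10% nesting
   cells) or unsuitable (U). Regional summaries report P_O (% observed)
   and P_S (% observed or suitable) per species with cross-species
   means; O union S estimates the fundamental niche, O the realized one.
   Two-sample Kolmogorov-Smirnov tests with Benjamini-Hochberg
   adjustment compare indicator distributions across the categories.

Real global datasets are large and access-restricted in parts, so the
package ships a first-class **synthetic-data generator**: a parametric
coastline with transects, AR(1) environmental node series around smooth
spatial fields (tide as a sinusoid), circular habitat patches, and
nesting presence drawn from a logistic model on percentile-scaled
indicators. The planted structure is known exactly, which makes every
downstream stage testable end to end. Readers accept a generic
normalized schema (CSV / GeoJSON), so real data can be plugged in by
matching the documented columns.

## Worked example

```python
from coastnest import importance, pipeline
from coastnest.clustering import SOMConfig

study = pipeline.run_study(seed=1)            # synthetic study area
result = pipeline.analyze_study(study.table, species="CM",
                                rf_config=importance.RFConfig(seed=1),
                                som_config=SOMConfig(seed=1))

top = result.importance.ranks.sort_values().index[:6]
print("cells:", len(study.table),
      "| nesting prevalence: %.1f%%" % (100 * study.table["nesting_CM"].mean()))
print("top-6 RF indicators:", list(top))
for ind in ("h_tide", "SST_med"):
    print(f"rho({ind}) = {result.correlation.rho[ind]:+.2f} "
          f"({result.correlation.category[ind]})")
print("Jaccard(O+S vs planted p>0.5): %.2f"
      % pipeline.recovery_jaccard(result, study.probabilities))
print(result.summary[["P_O_CM", "P_S_CM"]].round(1).to_string())
```

prints

```
cells: 479 | nesting prevalence: 15.0%
top-6 RF indicators: ['SST_med', 'D_sgr', 'h_tide', 'u_c_med', 'D_c_03', 'D_cor']
rho(h_tide) = -0.49 (significant)
rho(SST_med) = +0.61 (significant)
Jaccard(O+S vs planted p>0.5): 0.78
        P_O_CM  P_S_CM
region                
Global    15.0    18.4
```

The generator plants nesting on low tidal range and high sea surface
temperature; the pipeline recovers both drivers in the top three of 22
RF ranks, finds the planted correlation signs as significant at the
cluster level, and the recovered O+S set overlaps the planted
high-probability set with Jaccard 0.78. P_S > P_O quantifies the niche
headroom the suitability map identifies.

The same pipeline is available as CLI stages exchanging plain-text
artifacts (`coastnest synth`, `build-grid`, `derive-indicators`,
`importance`, `cluster`, `suitability`); see `coastnest --help`.

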