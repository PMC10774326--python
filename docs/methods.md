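# Methods

This note documents the models and procedures implemented in
`coastnest`, the parameters that matter, the synthetic study conditions,
and the numerical choices made where the design was genuinely open.

## Coastal-region grid

Shoreline transects (one per ~1 km of coast, carrying shoreline angle,
nearshore/backshore slope, maximum coastal elevation and % built
environment) are overlaid on a hexagonal tiling. Every cell covering at
least one transect centroid is a candidate coastal region.

**Hex backends.** Indexing is abstracted behind a `HexIndexer`
interface. The default backend tiles a local equirectangular projection
with regular pointy-top hexagons in axial coordinates (circumradius
26 km by default: vertex-to-vertex diameter 52 km, planar area
(3√3/2)·26² ≈ 1756 km²). Distortion grows with distance from the
reference latitude, so the backend targets latitude bands of a few tens
of degrees — matching the default working band of −39° to 48°, the span
of known nesting grounds plus buffer. An icosahedral H3 wrapper is
provided for environments where the `h3` library is installed; no part
of the pipeline or tests requires it.

**Refinement.** Cells representing only a few kilometres of coast are
removed greedily, fewest transects first: a cell is eligible when it has
fewer than `min_transects` (default 5) transects *and* fewer than
`min_neighbors` (default 1) coastal neighbors. A removal that would
leave a transect of a contiguous stretch farther than 100 km from every
surviving cell is skipped (the no-gap constraint); an isolated cell —
one with no coastal neighbors at all — may be removed even if its
transects end up unreachable, in which case they are dropped with a
logged warning. Transects of removed cells relink to the nearest
surviving cell within 100 km (inclusive), measured by the Haversine
distance to the cell's running coastline centroid. The resulting
invariant: every input transect is either linked to exactly one cell or
provably more than 100 km from all surviving cells.

**Coastline centroid (CLC).** The spherical mean of the linked transect
positions (mean of unit vectors, renormalized), which is immune to
longitude wrap-around at the date line. The CLC anchors node matching,
current/habitat proximity, and region membership.

**Nesting state.** Binary per species: a cell is a nesting region when
at least one nesting site of that species falls inside it, regardless of
the number of sites or turtles — a deliberate robustness choice against
heterogeneous monitoring effort. Sites falling in no coastal cell (e.g.
slightly offshore records) snap to the nearest CLC within `snap_km`
(default 25 km), else they are logged and ignored.

## The 22 indicators

Time-series indicators use the median as the measure of center and the
95th percentile as the measure of extremes; the peak-period standard
deviation flags bimodal (swell + wind-sea) wave climates, and the
circular standard deviation of shoreline angle measures coastline
complexity. Percentiles interpolate linearly between order statistics;
standard deviations use the n−1 divisor. All distances are great-circle
with R = 6371.0 km.

Node matching takes the k nearest nodes within 100 km of the CLC —
k = 1 for the wave class, 2 for atmospheric and ocean-current classes, 3
for the tide/surge class, reflecting source resolutions — with exact
distance ties broken by ascending node id. Statistics are computed per
node first, then averaged arithmetically over matched nodes; NaN-only
nodes are skipped, and a cell with no node in range gets NaN for that
class's indicators (NaN rows are excluded listwise from model fitting,
with counts logged).

Choices the source conventions leave open, all exposed in config:

* **Tidal range** (`h_tide`): mean over successive windows of one
  tidal-cycle length (default 24 h 50 min) of (window max − window min),
  computed per node then node-averaged. A pure sinusoid of amplitude A
  evaluated over full-cycle windows gives exactly 2A.
* **Current proximity** (`D_c_03`): distance to the nearest node whose
  median current speed is ≥ 0.3 m/s (inclusive), over all nodes of the
  dataset, NaN when none qualifies anywhere.
* **Habitat proximity** (`D_cor`, `D_sgr`): minimum distance to any
  polygon boundary vertex after densifying edges to ≤ 1 km; 0 inside a
  polygon.
* **Shoreline-angle dispersion** (`phi_std`): circular statistics by
  default ({359°, 1°} has dispersion ≈ 1°, not ≈ 179°); the plain linear
  convention is kept behind a flag for matching datasets computed that
  way.

`MADm` — median absolute deviation from the median, normalized by the
median — is provided as a robust, scale-free within-cell variability
measure (MADm = 1 means half the samples deviate from the median by
more than the median itself); it is undefined (NaN, warned) for zero
median and invariant to positive rescaling.

## Random-forest screening

One `RandomForestClassifier` per species (500 trees, √p features per
split, no depth cap, class-balanced weights — sized for single-digit
nesting prevalence), labels = binary nesting state. Importance is
normalized mean impurity decrease by default; permutation importance is
selectable (negative values clipped at zero before renormalizing), and
the type used is recorded in provenance. Precision, recall and F1 are
computed by predicting the training rows themselves: the forest is used
as a pattern detector on a fixed dataset, not as a predictive model, so
these scores are optimistic by construction and are labelled as such in
the output.

Robustness: a seeded 4-way partition; four sub-models, each trained on
three partitions; consistency is the Spearman correlation of each
sub-model's importances against the full model's.

Subset selection walks indicators by descending importance and skips any
whose |Spearman rho| against an already-selected indicator reaches 0.9 —
importance spread over a collinear pair reflects one underlying process,
so only one member is kept — stopping at six. An explicit per-species
override list replaces the automatic choice verbatim and is recorded;
this is the hook for expert judgment.

## Scaling, MaxDiss, SOM

**Percentile scaler.** z = (x − min)/(p99.9 − min) per indicator, fitted
on finite values; values above the 99.9th percentile exceed 1 (no
clipping). Robust to outliers and free of normality assumptions, unlike
min-max or standard scaling. A degenerate indicator (p99.9 = min) scales
to all zeros with a warning; an all-NaN indicator is an error naming it.

**MaxDiss initialization.** Greedy MaxMin: the first neuron is the row
maximizing total Euclidean distance to all rows; each next neuron
maximizes the minimum distance to those already selected; exact ties
break by ascending row index, making the selection deterministic and
prefix-stable (the first m of k selections do not depend on k). Note
that under ties different greedy-consistent tie-breaks can end with
different minimum pairwise distances; this implementation is the
lexicographically smallest greedy path, not a global optimum.

**SOM.** k = rows × cols neurons (default 13 × 13 = 169, the lattice
size is configurable; no automatic k selection is attempted) on a
rectangular lattice; the neighborhood kernel uses Euclidean distance on
integer (row, col) coordinates — hexagonal rendering of SOM lattices is
cosmetic. Online training: per sample, the best-matching unit b is the
nearest neuron and every neuron j moves toward the sample with gain
η(t)·exp(−d_lat(j,b)²/(2σ(t)²)). σ decays linearly from max(rows,cols)/2
to 0.2 and η from 0.5 to 0.01 over 200 epochs, with per-epoch sample
shuffling from the config seed (training is bitwise reproducible).

The final radius deliberately ends well below one lattice step: with a
final radius of 1, neighbor coupling (e^−0.5 ≈ 0.61) keeps the map
over-smoothed and the quantization error can end *above* that of a
well-spread initialization; a sub-lattice-step final radius turns late
training into near-quantizer refinement. Even so, a MaxDiss
initialization with k comparable to n is itself a near-optimal
quantizer, and the trained (topology-constrained) map is not guaranteed
to beat its raw quantization error — training improvement is guaranteed
in practice from unordered initializations, which is how the training
property is tested. Quantization error (mean distance of rows to their
best-matching units) is recorded per epoch. Empty clusters are allowed
and flagged; rows with NaN in any selected indicator are excluded from
scaling and training and labelled unclustered downstream (counted as
unsuitable in region denominators; exclusion is one config switch away).

## Correlation, suitability, summaries, KS

Cluster statistics: member count, nesting count, nesting percentage and
per-indicator medians; empty clusters are excluded from correlation.
Spearman's rho (average ranks for ties; NaN with a warning on constant
input) between cluster indicator medians and nesting percentages is
categorized as insignificant (|rho| < 0.1), weak ([0.1, 0.3)) or
significant (≥ 0.3, inclusive). P_n is the percentage of non-empty
clusters containing any nesting cell. Rank correlation detects monotone
relationships only; a driver that constrains nesting to an interior
range of its values can correlate near zero and still shape the
suitability map, because the SOM captures non-monotone structure.

Suitability per species: O for nesting cells; S for non-nesting members
of clusters whose nesting share reaches the threshold (default 10%,
inclusive); U otherwise. Raising the threshold never adds suitable
cells, and P_S ≥ P_O always.

Regions are user-supplied polygons; cells join a region by CLC
point-in-polygon, overlapping region polygons are an error, and a
"Global" row always covers all cells. The shipped
`regions_synthetic_demo.geojson` contains approximate hand-drawn
rectangles for eight ocean regions and is explicitly non-authoritative.
P_O and P_S are percentages of the region's cells; cross-species means
skip species with no observed nesting in the region (their cells are
dashes, not zeros, in a summary table); reported percentages round
half-even to one decimal at presentation time only.

KS comparisons: two-sample Kolmogorov–Smirnov per indicator for each
category pair (O|S, O|U, S|U), exact p-values when the smaller sample
has ≤ 25 members and asymptotic otherwise; the three p-values of each
indicator are Benjamini–Hochberg adjusted together (α = 0.05); a
category with fewer than two members skips its pairs with a warning.

## Synthetic study conditions

The generator is the package's test bed, not a statistical emulator of
any real dataset. What it emulates: the *structure* of the four input
classes and a known, recoverable indicator–nesting relationship. What it
does not: real marginal distributions, storms/cyclones, bathymetry,
shoreline change, nesting seasonality, spatial clustering of nesting
effort. Passing tests therefore demonstrate that the pipeline recovers
planted regional-scale structure through the full grid → indicators →
forest → SOM → suitability chain — not that any particular real-world
conclusion holds.

Default study area (`synth.default_config`): a ~16,600-km meandering
low-latitude coastline (transects every 1 km; ~480 cells after
gridding); environmental nodes follow the coast at 28–55 km spacing,
offset 10–25 km seaward so k-nearest matching is exercised nontrivially;
1440 hourly time steps (60 days) per series, AR(1) noise with burn-in
for stationarity; three coral and three seagrass circular patches
anchored to the coast. Sea surface temperature rises linearly 16 → 30 °C
along the coast while the tidal amplitude forms a broad mid-coast bulge
(base 0.15 m + 1.1 m Gaussian in alongshore position, width 0.3 of the
coast length), so the two planted drivers are distinct spatial fields
that both shape the boundary of the suitable set.

Nesting (green turtle by default) follows
p = expit(−6 − 12·z(h_tide) + 12·z(SST_med)) on percentile-scaled
indicators. The intercept is set so prevalence is ≈ 15%; the slopes are
steep so presence probabilities are near 0 or 1 for > 93% of cells,
which makes the planted high-probability set {p > 0.5} well defined as
ground truth for suitability recovery. Two deliberate design notes:
shallow slopes (|β| ≈ 3) leave the p > 0.5 set a small subset of the
prevalence set and make set-overlap evaluation ill-posed; and a tidal
field that varies only in a narrow stretch leaves most cells tied at the
base amplitude, so the planted marginal tide effect would be
unrecoverable by rank correlation in principle. The broad bulge and
steep slopes avoid both failure modes of the *evaluation*, not of the
method. Bernoulli draws are seeded; a deterministic threshold mode turns
the generator into an exactly invertible fixture for tests.

## Problem sizes and determinism

Tests and the acceptance script run the full-size synthetic study
(~480 cells, 22 indicators, 169-neuron maps) for the recovery checks and
smaller fixtures elsewhere; a single end-to-end analysis takes a few
seconds on one CPU. All randomness flows from explicit integer seeds
(generator streams are spawned per component; RF, partitioning and SOM
shuffling take seeds from their configs), and repeated runs are
bitwise-identical.

## Known limitations

* The planar hex backend distorts cells far from its reference latitude;
  global-scale runs on real data should use the H3 backend.
* Training-set RF scores overstate predictive skill by design; use the
  cross-validation report for robustness, not generalization claims.
* SOM cluster membership near cluster boundaries depends on the training
  schedule; quantities derived from it (rho, P_S) are stable in the
  planted-signal tests but individual cell labels are not contractual.
* The region summary treats unclustered (NaN-indicator) cells as
  unsuitable by default, which biases P_S downward where data coverage
  is poor.
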