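# Methods

## Problem and scope

`reserva` implements a raster-based systematic conservation planning
pipeline for a region where oil concessions ("blocks") overlap reserves
and biodiversity. The region is modeled on a regular square grid in an
abstract planar CRS with km units; there is no geodetic reprojection,
because all inputs are either synthetic or already aligned. Cells outside
the study mask are no-data in every layer, and the ecosystem map
partitions the mask.

## Planning units and lock rules

The study area is tessellated into square planning units (PUs) of
b × b cells, b = ⌈√(pu_area / cell_area)⌉, clipped to the mask. A PU
exists if *any* member cell is inside the mask (membership by cell, not
centroid), so fragmented margins are kept; its area is the member-cell
count times the cell area. Rook adjacency records shared edge lengths for
the optional boundary-length term.

A PU is "within" a zone when more than half of its member cells are — a
deterministic majority rule. Lock states:

- protected-zone PUs → locked in, in every scenario;
- high-impact PUs (majority of cells above the risk threshold) → locked
  out, in every scenario;
- oil-block PUs → locked out per scenario: 1 = operative + southern
  blocks, 2 = operative only, 3 = none.

When a PU qualifies for both states (reserves overlap operative blocks),
locked-in wins: reserves are forced into every solution even where they
coincide with concessions. The precedence is an argument for sensitivity
runs.

## Features and targets

Species features are thresholded suitability surfaces (default threshold
0.5 on [0, 1] surfaces; a continuous mode sums raw suitabilities instead —
both are supported because either convention is defensible for stacked
species-distribution models). Ecosystem features are categorical cells.
Amounts are km² per PU; a feature's "protected amount" is what already
sits in locked-in PUs, and target achievement starts from there.

The target fraction for a feature of extent A is piecewise linear:
s·t_max below A_small, s·t_min above A_large, linearly interpolated
between, with (t_max, t_min) = (0.90, 0.10), species thresholds
(10,000, 75,000) km², ecosystem thresholds (100, 10,000) km², and the
scenario scale s ∈ {1.0, 0.8, 0.6, 0.4}. The boundary value at a
threshold equals the endpoint (the interpolant is continuous, so the
convention is unambiguous). "Half targets" divides s by two — 0.4 becomes
0.2, i.e. an 18–2% gradient — because halving applies to the scheme
already chosen. A feature is "met" when achieved ≥ target × (1 − 1e-9);
the relative slack absorbs float accumulation over thousands of PU sums.

At the generator's desk scale (10,000 km² maps) the pipeline default
rescales the species thresholds tenfold, to (1,000, 7,500) km², keeping
the same position of the thresholds relative to the map extent; the
ecosystem thresholds already fit the desk-scale ecosystem sizes and are
kept.

Extents include deforested cells by default (a flagged alternative would
exclude them); the exclusion of degraded land from *selection* is handled
by the risk surface instead.

## Environmental risk surface (ERS)

Point threats (wells, dams, airports, mines) and line threats (roads) are
rasterized and decayed with distance to the nearest source — linear
max(0, 1 − d/r) by default, exponential optional, exactly zero beyond the
decay radius. Because the kernels are monotone, the nearest-source
distance makes a multi-source footprint equal the cellwise max over
single sources. Field threats (population, agriculture) pass through
normalized to [0, 1]. The composite is the weight-normalized sum rescaled
so zero threat → 0 and all-threats-at-max → 100, clipped to [0, 100].

Weights (equal), kernels (linear) and radii (roads 2 km, wells 1 km,
dams/airports 5 km, mines 2 km) are declared stand-ins exposed in
configuration, not calibrated values. Cells with ERS strictly greater
than 32 are "high impact". PU cost is the mean ERS over member cells
floored at ε = 0.01: pristine PUs must keep positive cost or the
minimum-set objective becomes degenerate (adding a free PU would never be
penalized).

## Selection

Objective for a selection S ⊇ locked-in, disjoint from locked-out:

    score(S) = Σ cost(S)
             + Σ_f spf_f · cost_scale · max(0, target_f − achieved_f(S)) / target_f
             + blm · boundary(S)

The shortfall is normalized by the target so restricted-range features are
not dominated by widespread ones. `cost_scale` converts the dimensionless
shortfall to cost units: mean PU cost × ⌈max_f target_f / mean PU area⌉
(a PUs-needed heuristic — the documented constant formula). With the
default uniform spf = 10, one fully unmet feature costs ten times that
estimated solution cost. blm defaults to 0 (no compactness pressure).
Locked-out PUs carry no creditable amount.

Annealing proposes single-PU add/remove flips on available PUs only,
starting from a seeded random half-density selection. The initial
temperature is adaptive — 5 × the mean |Δ| of 64 probe flips, putting
typical worsening moves near 80% initial acceptance — with geometric
cooling to 1e-6 of the initial temperature over `n_iter` proposals.
Because the walk can visit a better basin and drift away before the
temperature pins it, the best state ever seen (the incumbent) is kept;
both the final state and the incumbent get a greedy pass that removes any
PU whose removal lowers the objective, and the better of the two is
returned. Runs are deterministic for a fixed seed. If targets are
unreachable even selecting everything available, the returned solution
flags the unmet features rather than raising.

A vectorized exhaustive enumerator (≤ 20 available PUs, ties broken by
the lexicographically smallest selected-id tuple) serves as an
independent optimum oracle; on 100 seeded 15-PU instances with large spf
the annealer at 30,000 proposals matches it in ≥ 95 (observed: all) runs.

Replicates seeded base_seed + k give the summed solution (per-PU selection
frequency); priority areas are PUs selected in ≥ 75% of replicates
(inclusive threshold). Target representation is reported from the best
replicate — the network one would actually implement — while the summed
solution maps irreplaceability; with many interchangeable near-optimal
covers, frequency thresholding alone systematically understates what any
single implemented network achieves.

Defaults n_iter = 100,000 proposals and 100 replicates are stand-ins (the
reference workflow's annealing parameters are unreported); tests and the
scenario experiments run reduced sizes (30,000–60,000 proposals, 6–8
replicates, 100×100-cell landscapes with 75 species + 25 ecosystems,
~2,500 PUs of 4 km²) chosen so each suite completes on one CPU while the
solver is still converged at the instance sizes involved.

## Richness center

Per-group richness maps are cellwise sums of thresholded presence
rasters. The upper-tertile mask keeps cells at or above the nearest-rank
2/3 quantile, computed over cells with positive richness: with large
zero fractions the literal all-cells tertile can include zeros, which
contradicts "highest diversity" (a flag restores the all-cells
quantile). Ties at the cut are kept, so a constant map is wholly in its
top class. The richness center is the intersection of all group tertile
masks; its vulnerability is the percent of center cells inside blocks ∪
deforestation, and inside protected zones, at one decimal.

## Overlap accounting

All extents are cell counts × cell area (exact at grid resolution; no
sub-cell vector areas). Tables report km² to the nearest integer and
percentages with half-up rounding to the nearest integer (two decimals
for the reserve-in-southern-blocks row, which is genuinely sub-percent),
matching the precision conventions of published concession accounting.
Ecosystem protection is measured against protected zones free of blocks
and deforestation — the effectively protected estate.

## Block importance

Four per-block variables: (1) species diversity = mean of the min–max
normalized (across blocks) zonal means of total and priority-species
richness — the combination rule is a declared choice since only "a
combination" is specified; a constant metric normalizes to zero;
(2) number of ecosystems present; (3) preservation = non-deforested
fraction; (4) fraction inside priority areas (scenario 3) or protected
zones. Each variable is quartile-scored 1–4 by nearest-rank cuts, ties
sharing the *lower* score (ambiguous blocks are not inflated; all-equal
inputs all score 1), and the index is the sum (4–16).

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes,
per layer from an independent RNG sub-stream keyed by (seed, CRC32 of the
layer name) — adding a layer never perturbs the others.

- **Mask**: smoothed-noise carving of the map edges (~80% coverage), or a
  full rectangle.
- **Ecosystems**: Voronoi partition around K seeded centers — exactly K
  nonempty categories.
- **Species**: anisotropic Gaussian suitability bumps with low-amplitude
  smooth noise. The 0.5 contour is calibrated by nearest-rank quantile of
  the Mahalanobis field *within the mask*, so the thresholded extent hits
  the requested range size even under edge clipping (observed error well
  inside the ±20% contract; the log-uniform range-size spectrum is
  recovered with KS distance < 0.2 at n ≥ 50). Range centers follow a
  north-biased exponential gradient so a richness center exists by
  construction; optional fractions of each group are confined to the
  southern blocks (southern endemics) or centered in a shared northern
  hotspot window.
- **Zones**: rectangles jittered inside shuffled grid slots (disjoint
  within a category by construction, error on infeasible packing), block
  areas capped at 2,000 km² (the concession cap of 200,000 ha), southern
  blocks confined to the southern half; reserves may straddle operative
  blocks; untouchable areas nest inside reserves.
- **Threats**: Poisson point sets (wells inside operative blocks), jittered
  west–east road transects, smoothed random fields.
- **Deforestation**: the requested fraction of the mask nearest to roads
  and wells (distance-transform quantile).

`make_paper_mimic` lays zones out deterministically at any grid size:
operative blocks tile the northern 32% of the map, southern blocks the
southern 36% (68% total), five reserves and two untouchable areas give
22.5% protected zones with 27.8% of them inside blocks — inside the ±3
percentage-point bands of the reference proportions. Sixty percent of
each species group is centered in a hotspot window inside the operative
band and the block-free band just south of it is treated as the old
deforestation frontier, so the multi-group richness center falls inside
blocks ∪ deforestation by construction (observed 100% across seeds
0–15). A fifth of each group is confined to the southern blocks, which
makes the scenario contrast observable: those features cannot be met in
scenario 1, can in scenarios 2–3.

### What the mimic does and does not show

Passing tests on the mimic demonstrate the *mechanics* — lock-rule
semantics, target arithmetic, solver correctness, the qualitative
scenario gradient (met share scenario 1 ≤ 2 ≤ 3, with scenario 3
complete), and half-target monotonicity. They do not reproduce the
reference region's headline figures (absolute extents, the 45%/93%/33%
scenario numbers, specific block rankings), which depend on proprietary
geodata; species ranges here are unimodal bumps without climatic
covariates, sampling bias, or range fragmentation, and threat layers are
statistical stand-ins.

## Numerical choices and degenerate inputs

- Quantiles (tertile, quartile) are nearest-rank: deterministic and
  oracle-checkable against sort-and-cut.
- Percent rounding is half-up (not banker's), to match printed-table
  conventions.
- Annealer tie at Δ = 0 counts as acceptable (always accepted).
- Enumeration ties break lexicographically on selected ids.
- All-zero richness maps yield an empty tertile with a warning; an empty
  richness center reports (0, 0) vulnerability with a warning.
- Zero-extent features, empty masks, misaligned layers, unknown
  scenarios, and all-zero threat weights raise errors naming the culprit.

## Known limitations

- The annealer is a serial Python loop; at the default 100,000 proposals
  and 100 replicates a full three-scenario run takes minutes, not
  seconds.
- Priority-area frequency thresholds understate achievable representation
  when many near-optimal covers exist (hence best-replicate reporting).
- Raster I/O uses ESRI ASCII grids and GeoJSON: portable and exact, but
  large rasters are bulky; no compressed formats are written.
- `table1`/`table2` operate on zone rasters; polygon inputs are
  rasterized by cell-center containment, so sub-cell sliver overlaps are
  not resolved.
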