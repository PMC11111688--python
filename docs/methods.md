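# Methods

## Model

The pipeline estimates the long-term carbon-storage loss caused by plant
biodiversity loss under a climate/land-use scenario, in four stages.

**Effective habitat area.** Compositional similarity between cells stands in
for shared species: the effective area of environments similar to cell *j*
is `E_j = Σ_i s(x_j, x_i) A_i`, summing over all cells (including *j*) with
`A_i` the spherical cell area. The reference state hypothetically assumes
all habitat in perfect condition. The scenario state uses each cell's
*future* environment and discounts by projected habitat condition:
`E*_j = Σ_i s(x_j, x_i') h_i A_i`. "Similar environment" is treated
continuously (similarity-weighted sums), not with a similarity cutoff — the
continuous reading avoids an arbitrary threshold and makes both quantities
linear in condition, which the tests exploit.

**Similarity kernel.** A fitted generalized dissimilarity model is out of
scope; the kernel is a pluggable interface whose default is
`s(x, y) = exp(−Σ_d |x_d − y_d|/σ_d)`. It satisfies the contract the
pipeline needs — `s(x,x) = 1`, symmetry, values in [0, 1], monotone decay
with environmental distance — and σ (default 1, per standardized covariate
dimension) sets how quickly compositional similarity falls off. Any object
implementing `pairwise(X, Y)` with that contract can replace it.

**Species-area persistence.** `p = (E*/E)^z`, with `z = 0.25` (the standard
fragmentation exponent). Intact habitat also relaxes toward equilibrium
richness (`z ≈ 0.15`), so the *additional* loss from climate and land-use
change is bounded below by the difference, `z = 0.1`; the envelope sweeps
`z ∈ [0.1, 0.65]`. Ratios above 1 (expanding environments) are propagated,
not clipped — per-region persistence above 1 is legal output and downstream
stages interpret it as a gain. Whether per-cell persistence should be capped
at 1 before aggregation is ambiguous in the source material; we propagate
gains, consistent with reported negative losses.

**Ecoregion aggregation.** Per-region persistence is the weighted geometric
mean `exp(Σ w ln p / Σ w)` with `w_j = 1/E_j`: cells in less extensive
environments likely hold more unique species and weigh more. Weights are
reported normalized to sum to 1 within each region; the mean is invariant to
their rescaling. Inside the logarithm p is floored at ε = 1e-9
(configurable): without a floor a single p = 0 cell collapses the whole
region to zero regardless of the other cells.

**Biomass.** `p_biomass = p_region^b`, from the empirical power law
`Biomass = a·richness^b`; `a` cancels in the ratio. Central `b = 0.26`, 95%
CI (0.16, 0.37), carried as the envelope range. b is a global scalar — the
CI is wider than spatially explicit estimates, so it already spans spatial
variation. The transform is applied to *per-region* persistence; the
`jensen_gap` diagnostic reports the (small, concavity-driven) difference
between transforming the cross-region mean and averaging the per-region
transforms, since summaries can be read either way.

**Carbon.** `ΔC = S(1 − p_biomass)` in kg C/m², with S = cVeg or
cVeg + cSoil after soil masking. Gleysols (wetland), Histosols (peatland)
and Cryosols (permafrost) are excluded from the soil term — their carbon is
governed by drying/warming rather than plant diversity — by zeroing their
cSoil contribution (vegetation carbon on those cells still counts). Unknown
class codes warn and are kept. Totals: `C_total = 10⁻¹² Σ_k ΔC_k A_k` (kg →
Pg) per ecoregion and summed globally. Negative ΔC (gains) is kept in the
sums by default; `clip_gains=True` floors per-cell ΔC at zero for the
alternative reading. Missing-carbon cells are skipped and their area
reported.

## Numerical and geometric choices

- **Cell areas**: spherical Earth, `A = R²Δλ(sin φ_top − sin φ_bottom)`,
  R = 6 371 000 m. The sub-0.3% ellipsoidal error is far below the method's
  parametric uncertainty. Grids are cell-edge registered, rows ordered
  north → south, longitudes in [−180, 180).
- **Resampling**: categorical rasters nearest-neighbour only (bilinear on
  class codes is rejected); continuous rasters default to bilinear on cell
  centres. NaN propagates through any bilinear stencil that touches it;
  target centres outside the source-centre hull take the nearest edge value.
  The prescribed order is: soil classes → carbon grid (nearest), mask, then
  carbon → analysis grid (bilinear).
- **Pairwise complexity**: effective areas are O(n²) in cell count,
  vectorized; fine for desk-scale grids (≤ 100×100 ≈ 10⁴ cells). Larger
  grids would need tiling, which changes performance, not semantics.
- **Envelope**: 5×5 (z, b) grid, always including the four corners and the
  central pair (0.25, 0.26). Coarse on purpose: on loss-only worlds the
  surface is smooth and monotone in both exponents, so the extremes sit at
  the corners (asserted by tests rather than assumed).

## Synthetic worlds

`make_world(seed, ...)` generates everything downstream stages consume. All
randomness derives from one `numpy.random.SeedSequence` split per component;
same seed and parameters give bit-identical worlds.

- **Ecoregions**: seeded flood fill from random cells with random
  tie-breaking — contiguous regions of unequal area, which the
  loss-by-area curves need.
- **Environment**: each covariate dimension is a sum of four random
  low-frequency sinusoids, standardized; smoothness makes the kernel produce
  graded beta diversity. The future field adds `climate_shift` times another
  smooth pattern (plus optional iid noise), so regions are forced unevenly.
- **Condition**: the present defaults to pristine (1.0 everywhere), matching
  the reference effective-area assumption so that a zero-change scenario
  yields persistence exactly 1; `present_condition_loss` degrades it when
  wanted. The future multiplies by `1 − condition_loss·g` with g a smooth
  mean-1 pattern, so the mean relative reduction equals `condition_loss`.
- **Carbon**: vegetation carbon peaks in a tropical band
  (`12·exp(−(lat/30)²)` kg C/m² times a smooth texture, a realistic tropical
  forest magnitude); soil carbon increases poleward. The world is all land,
  so *global* totals exceed real-Earth values even though per-m² stocks are
  realistic.
- **Soils**: quantile slices of a smooth field plus polar bands give the six
  WRB-style classes, including the three excluded ones (~21% wetland/peat by
  construction, plus polar Cryosols).
- **Scenario presets**: `global_sustainability`
  (climate_shift 1.25, condition_loss 0.25) and `fossil_fueled`
  (1.5, 0.35), chosen once so that ecoregion-mean species loss across seeds
  sits near 16% and 21% respectively — the severity levels the two study
  scenarios exhibit. Default world size 24×36 cells, 24 ecoregions, 2
  environmental dimensions: large enough for varied region sizes, small
  enough that the O(n²) stage stays instant.
- **Embedded power law**: per-region persistence values are drawn in
  [0.5, 1.2] and the matching biomass fractions computed with a known
  `true_b` (optionally with log-normal noise), so regression-based parameter
  recovery can be verified exactly in the noise-free case.

What the generator does *not* emulate: real ecoregion geometry, realistic
beta-diversity structure from occurrence data, ocean/land masks, scenario-
dependent carbon baselines, or any correlation between soil class and
carbon stocks. Passing tests therefore certify the machinery — linearity,
aggregation, accounting, propagation — not the realism of any particular
global PgC value.

## Problem sizes used by tests and the acceptance run

Unit and property tests run on grids from 1×1 up to 20×20 with hundreds of
seeded worlds; the oracle-equivalence suite checks 200 worlds of 3–6 cells
per side against explicit double-loop brute force at 1e-12 relative. The
analysis drivers use the 24×36 default world. These sizes were chosen as the
smallest that exercise every code path with non-trivial spatial structure.

## Known limitations

- The default kernel is a stand-in: absolute persistence values depend on σ
  and carry no empirical calibration; only the structure of the chain is
  validated.
- Aggregation area per ecoregion is the mapped area intersected with cells
  carrying non-missing carbon (the "mapped area" reading); an optional
  habitat-condition weighting of areas is not currently implemented.
- Litter carbon is not modelled; soil-carbon response is assumed to scale
  like biomass when included, which is an upper-bound-style assumption.
- Boundary cells after resampling keep the nearest-neighbour majority label;
  no sub-cell area weighting.
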