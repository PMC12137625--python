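# Methods

This note documents the models, conventions, and design choices behind
`surveygap`, in the spirit of a package vignette: what is computed, under
which assumptions, and what the synthetic validation does and does not
establish.

## Completeness accounting

Analysis cells are a planar equal-area lattice (`GridSystem`), 0-based
`(row, col)` ids, half-open cell extents (a point on a shared boundary
belongs to the cell above/right of it). Real-world inputs are assumed to
be in an equal-area projection; the simulator works in abstract planar
units.

Per cell, `S_original` counts recorded species, `S_potential` counts
model-predicted species, and `S_r` their union, each species once.
Completeness is `V_c = S_original / S_r`, incompleteness `V_inc = 1 − V_c`.
Two conventions matter:

* **Empty cells are missing, not complete.** A cell with `S_r = 0` has no
  evidence either way and is reported as NaN, distinct from a surveyed
  cell whose records cover every predicted species (`V_inc = 0`).
* **Occupancy for weighted richness.** `WR = Σ 1/c_i` needs `c_i`, the
  number of "sites" a species occupies. The default counts occupied cells
  on the union (recorded ∪ predicted) ranges, which keeps WR defined in
  never-visited cells; `occupancy_basis="recorded"` restricts it to
  recorded cells. Neither reading is privileged; both are exposed.

Conservation identity used as a cross-check throughout: summing WR over
all cells returns exactly the number of species with a non-empty range,
because each species contributes `c_i × (1/c_i) = 1`.

Priority maps use exact Fisher–Jenks natural breaks (dynamic programme
over sorted values minimising within-class sum of squared deviations;
ties resolved toward the earliest split). Classification intervals are
open on the left and closed on the right, the last class unbounded.

## Ensemble distribution models

Per species with ≥ 5 occupied raster cells: presences plus 500 uniformly
drawn pseudo-absence cells (per repeat, excluding presences, no
geographic buffer), a stratified 75/25 train/evaluation split, three
repeats, three learners (L2 logistic regression, random forest,
gradient-boosted trees — a pluggable registry; the ensemble mechanics,
not the roster, are the tested content). Each member is scored by the
true skill statistic at the max-TSS threshold on its evaluation split;
members with TSS ≥ 0.7 are retained and averaged with weights
proportional to TSS. Cells with ensemble suitability ≥ 0.66 form the
predicted range; the 0.05 / 0.33 / 0.66 suitability classes are also
provided. Species below the record floor — and species for which no
member clears the TSS bar — fall back to their recorded cells as their
range, flagged in the model report. Per-species seeds derive from
`(global seed, species index in sorted order)`, so results do not depend
on iteration order.

On a 20 × 20 grid there are fewer than 500 candidate cells, so all
non-presence cells serve as pseudo-absences (with a warning); this is the
intended degradation, not an error.

## Driver attribution

The response is `log10(V_inc + 1)` over complete-case cells (any cell
with missing response or covariates is dropped and counted). Covariates
are `log10(n+1)`-transformed (all are nonnegative densities/fractions)
and z-scored so coefficients are comparable across models.

* **AIC convention**: `AIC = n·ln(RSS/n) + 2(p + 2)`, counting intercept
  and error variance. Stepwise selection starts from the full model and
  applies the best single add/drop move until no move improves AIC; ties
  prefer drops, then column order. The same constant is used by the
  all-subsets oracle in the tests, making comparisons exact. The pipeline
  additionally reports a full-likelihood-scale OLS AIC
  (`−2ℓ + 2(p+2)`) so OLS and SAR AICs are directly comparable.
* **LMG** is computed by the exact 2^p subset decomposition (p ≤ 12);
  shares sum to the full-model R².
* **SAR error model** `y = Xβ + u, u = λWu + ε`: queen-contiguity
  weights on the analysis lattice, row-standardised; the concentrated
  log-likelihood is profiled over λ ∈ (−0.999, 0.999) using
  `log|I − λW| = Σ log(1 − λω_i)` with the eigenvalues of the
  row-standardised W obtained through the symmetric similarity transform
  (dense eigendecomposition; fine to a few thousand cells). A coarse grid
  plus bounded refinement keeps the search deterministic; the λ = 0 point
  is always evaluated so the fitted likelihood never falls below the OLS
  likelihood. β covariance is the asymptotic `σ²(X*'X*)⁻¹` with normal
  p-values; R² is reported as the squared correlation of the trend Xβ
  with y (a pseudo-R²; SAR has no variance decomposition). `lam=0.0`
  fixes λ and reproduces OLS exactly.
* **Variance partitioning** fits the seven regressions on all non-empty
  unions of the three covariate groups, converts each to adjusted R²
  (vegan's convention; raw R² via `mode="raw"`), and solves the
  inclusion–exclusion system for unique, pairwise, and triple fractions.
  Individual adjusted-scale fractions can be slightly negative; the seven
  fractions plus the residual sum to 1 by construction.
* If incompleteness has zero variance across evaluated cells (e.g. after
  a census), the driver stage is skipped: a constant response has nothing
  to attribute, and the SAR likelihood would degenerate.

## Water frequency

Frequency = water observations / valid observations per pixel; pixels
with no valid observation are missing. "Permanent" requires frequency
strictly above 0.75; "seasonal" covers the closed interval [0.25, 0.75];
frequencies below 0.25 carry no class (ephemeral water ignored). QA
screening drops an observation when any contaminant confidence is
strictly above 0.66. Inundation extent per analysis cell is
seasonal / (seasonal + permanent) pixel counts, missing where a cell has
no water pixel. These boundary readings (strict ">" for permanent and for
QA exclusion, closed seasonal interval) are fixed here and asserted in
tests.

## The virtual-ecologist simulator

What it emulates, and the default study conditions (chosen once):

* **Landscape**: 20 × 20 cells of size 100 (mirroring a 100-km lattice at
  plateau scale); 4 environmental layers as z-scored Gaussian random
  fields (white noise smoothed with σ = 3 cells — the simplest
  controllable autocorrelation mechanism); 3 drivers in each of the
  safety / attractiveness / accessibility groups, generated as
  `10·exp(z)` of independent smoothed fields so they are nonnegative and
  right-skewed like the densities and risk indices they stand in for
  (which also makes the log10(n+1) transform meaningful).
* **Species**: 30 species; logistic suitability with N(0, 1.5)
  coefficients over the environmental layers; intercepts calibrated by
  root-finding so each species' expected prevalence hits a target drawn
  from [0.05, 0.5]; presence is a Bernoulli draw from suitability
  (stochastic rather than thresholded, so repeat experiments are
  meaningful and prevalence is tunable).
* **Collection**: 4000 collection events allocated multinomially over
  cells with weights `∝ exp(Σ b_d · z(driver_d))`; at every visit each
  truly present species is recorded with detection probability 0.8;
  record coordinates are jittered uniformly within the cell so the
  point-to-cell assignment is exercised. The default bias is −0.9 on each
  safety driver vs +0.3 on the others — the 3:1 dominance of safety that
  the headline-structure experiment is designed to recover. The
  exponential-linear effort model and the single global detection
  probability are this package's choices; no canonical effort or
  detectability model exists for specimen collection, and none is claimed.
  An `exhaustive` design (every cell visited once) with detection 1 gives
  the census limit in which median `V_inc` must be exactly 0.
* **QA stacks**: per pixel, valid ~ Binomial(n_obs, 1 − cloud_prob),
  water ~ Binomial(valid, water_prob).

What it does **not** emulate: taxonomic error and name-resolution
ambiguity, per-species detectability, temporal/phenological structure,
real geography (projections, coastlines), or spatially structured
covariate measurement error. Passing the synthetic validation therefore
shows that the estimators are correct under their own assumptions — not
that a real campaign satisfies those assumptions.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` recompute: formula fixtures
(exact to 1e-12); the WR conservation identity; Jenks vs exhaustive
contiguous partitioning (n ≤ 15, k ∈ {2,3,4}); LMG vs direct p!-ordering
enumeration (p ≤ 5); stepwise-AIC vs the 2⁶ all-subsets optimum (≥ 18/20
designs); SAR nesting of OLS (λ fixed at 0, agreement to 1e-6),
near-unbiasedness of λ̂ on λ = 0 data (mean over seeds), and recovery of
λ = 0.6 at n = 400 over 20 seeds; variance-partition overlap ≈ 0 under
orthogonal groups and exact unit sum; ensemble recovery of a
strong-signal virtual species (all retained members TSS ≥ 0.7, Jaccard of
predicted vs true range > 0.5, monotone range shrinkage in the
threshold); the census limit; and safety-first variance-partition ranking
in ≥ 16/20 replicate biased surveys. Replicated experiments use the
oracle predictor (true ranges in place of fitted ensembles) so the chain
under test — bias → effort → incompleteness → attribution — is isolated
from SDM skill, which is validated separately. Grid sizes of 20 × 20 /
30 × 30 keep each experiment in seconds while leaving hundreds of cells
for the spatial statistics.

## Known limitations

* The SAR eigenvalue route is dense; beyond a few thousand cells a sparse
  log-determinant (e.g. Cholesky-based) would be needed.
* The collinearity filter is greedy and order-dependent by design (the
  priority order is the user's variable ranking); it does not search for
  the maximum retained set.
* Pseudo-absence sampling has no geographic exclusion buffer.
* Name cleaning is token-based (rank-marker stripping), not a taxonomic
  backbone lookup; GeoTIFF I/O is not supported — rasters travel as
  ESRI-ASCII grids.
* With a fitted (rather than oracle) predictor, `V_inc` conflates true
  sampling gaps with SDM false positives; on well-surveyed synthetic
  campaigns the fitted-SDM incompleteness is accordingly small and its
  driver signal weaker than under the oracle.
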