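# surveygap

Inventory-gap analysis for species collection data: where have collectors
*not* been, why, and where should the next expedition go?

Natural-history records (herbarium specimens, survey plots, database
occurrences) are the raw evidence behind most large-scale biodiversity
analyses, but they are collected opportunistically: accessible, attractive,
and safe places are over-sampled, while remote, risky terrain goes
unrecorded. `surveygap` implements a grid-based workflow that quantifies
this gap for a regional flora or fauna and attributes it to its drivers.
It is aimed at biodiversity informaticians and macroecologists working
with occurrence tables plus gridded environmental covariates.

## The method

On an equal-area analysis grid (100 × 100 km by default):

1. **Recorded richness** `S_original` — species actually collected in the
   cell, after cleaning (flagged records removed, infraspecific names
   merged to binomials, duplicates collapsed) and per-cell spatial
   thinning.
2. **Predicted richness** `S_potential` — species whose TSS-weighted
   ensemble distribution model (logistic regression, random forest, and
   gradient-boosted trees by default; members retained iff TSS ≥ 0.7 on a
   held-out 25% split, three repeats with 500 pseudo-absences each)
   assigns the cell suitability ≥ 0.66. Species with fewer than five
   records keep their recorded cells as their range.
3. **Completeness** — with `S_r` the union richness (each species counted
   once):

       V_c  = S_original / S_r          (collection completeness)
       V_inc = 1 − V_c                  (inventory incompleteness)

4. **Collection priority** — with `c_i` the number of cells occupied by
   species *i*, weighted (range-size-rarity) richness and priority are

       WR = Σ_i 1 / c_i                 P = WR × V_inc

   so cells that are both under-surveyed and rich in narrow-ranged
   species rank first; maps are classed with exact Fisher–Jenks natural
   breaks.
5. **Driver attribution** — `log10(V_inc + 1)` is regressed on
   standardized covariates grouped as *safety*, *attractiveness*, and
   *accessibility*: single-predictor OLS, LMG relative-importance
   decomposition of R², stepwise-AIC model selection, a maximum-likelihood
   spatial simultaneous autoregressive (SAR) error model
   `y = Xβ + u, u = λWu + ε` on queen-contiguity weights, and a three-set
   variance partition on adjusted R².
6. **Water frequency** (optional covariate stage) — per-pixel
   water-occurrence frequency from QA-screened observation stacks,
   permanent (> 75%) vs seasonal (25–75%) classes, and per-cell inundation
   extent IE = seasonal / (seasonal + permanent).

Because real campaigns come without ground truth, the package ships a
first-class **virtual-ecologist simulator**: known landscapes, known
species ranges (logistic suitability → Bernoulli presence), and a
collection process whose effort follows `exp(Σ b_d · z(driver_d))` with a
fixed detection probability. Every stage can therefore be validated
against truth, from range recovery (Jaccard overlap) to the recovery of
"safety drivers dominate incompleteness" structure.

## Worked example

`examples/03_completeness_priority.py` simulates a biased survey of 30
species on a 20 × 20 grid (collectors repelled by safety drivers 3× more
strongly than they are drawn by accessibility or attractiveness) and
scores every cell against the species' true ranges. It prints:

```
evaluated cells: 400 of 400
inventory incompleteness: median 0.000, mean 0.262, max 1.00
completely surveyed cells (V_inc = 0): 253
weighted richness range: 0.01 .. 0.21 (sum = 30.0 = number of species, a conservation check)

top-priority cells (P = WR x V_inc, Jenks class 4 = highest):
  cell ( 0,18)  S_orig  0 / S_r 15  V_inc 1.00  WR 0.21  P 0.21  class 4
  ...
```

Most cells are fully inventoried (the campaign spent 2000 collection
events on 400 cells), but avoided cells have `V_inc = 1` — nothing of
their true flora was recorded — and the priority score singles out those
that also hold narrow-ranged species. The WR column sums to exactly the
number of species, since each species distributes a total weight of 1
across its range. `examples/04_driver_attribution.py` continues to the
regression stage and prints the variance partition
(`safety 0.365 > accessibility 0.274 > attractiveness 0.015`), recovering
the simulated dominance of safety drivers.

The other examples cover the biased-sampling simulator, a single-species
ensemble fit, the water-frequency stage, and the one-call
`simulate_and_run` pipeline. A thin CLI wraps the same machinery
(`surveygap demo --seed 1 --outdir out/`, plus `simulate`, `prep`, `sdm`,
`completeness`, `drivers`, `water`, `run` subcommands).

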