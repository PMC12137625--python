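"""Why are some cells under-surveyed? Driver attribution for V_inc.

Regresses log10(V_inc + 1) on the ten-style driver covariates: simple OLS
per driver, LMG relative importance, stepwise-AIC model selection, a
spatial SAR error model on the selected terms, and a three-set variance
partition among safety / attractiveness / accessibility.
"""

import numpy as np
import pandas as pd

import surveygap as sg
from surveygap.completeness import summarize_cells
from surveygap.drivers import (build_weights, fit_sar_error, lmg_importance,
                               simple_ols, stepwise_aic, variance_partition)
from surveygap.envstack import log10p1, standardize
from surveygap.occurrences import assign_to_grid

landscape = sg.generate_landscape(20, 20, n_env=4, n_drivers_per_group=3,
                                  smoothness=3.0, seed=4)
species = sg.generate_species(landscape, 30, seed=5)
design = sg.SamplingDesign(total_effort=4000, detection_prob=0.8, seed=6)
bias = {name: {"safety": -0.9, "attractiveness": 0.3, "accessibility": 0.3}[g]
        for name, g in landscape.driver_groups.items()}
records = sg.sample_occurrences(species, design, bias, landscape)

recorded = assign_to_grid(records, landscape.grid)
truth = {sp.species_id: sp.presence_cells() for sp in species}
cs = summarize_cells(recorded, truth, landscape.grid)
cov = pd.DataFrame({n: layer.ravel() for n, layer in landscape.driver_layers.items()})
data = pd.concat([cs.reset_index(drop=True), cov], axis=1).dropna(subset=["V_inc"])

y = log10p1(data["V_inc"])
y_std = ((y - y.mean()) / y.std(ddof=1)).to_numpy()
X = standardize(log10p1(data[list(landscape.driver_layers)]))

print("single-predictor OLS on log10(n+1) scale:")
for name in X.columns:
    slope, _, r2, p = simple_ols(y, log10p1(data[name]))
    print(f"  {name:20s} slope {slope:+.3f}  R2 {r2:.3f}  p {p:.2g}")

print("\nLMG relative importance (shares of the full-model R2):")
print(lmg_importance(y_std, X).sort_values(ascending=False)
      .round(3).to_string())

selected, ols_fit = stepwise_aic(y_std, X)
weights = build_weights([(int(r), int(c))
                         for r, c in zip(data.cell_row, data.cell_col)])
sar_fit = fit_sar_error(y_std, X[selected], weights)
print(f"\nstepwise-AIC keeps {selected}; OLS R2 {ols_fit.r2:.3f}")
print(f"SAR error model: lambda {sar_fit.lam:.2f}, pseudo-R2 {sar_fit.r2:.3f}")

groups = {g: X[[n for n, grp in landscape.driver_groups.items() if grp == g]]
          for g in ("safety", "attractiveness", "accessibility")}
vp = variance_partition(y_std, groups)
print("\nvariance partition (marginal adjusted R2 per driver group):")
for g, total in sorted(vp.group_totals.items(), key=lambda kv: -kv[1]):
    print(f"  {g:15s} {total:.3f}")
print("safety tops the ranking because the simulated collectors avoided")
print("high-risk cells three times as strongly as any other preference.")
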