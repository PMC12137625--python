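"""Grid-cell inventory statistics: completeness, weighted richness,
collection priority, and natural-breaks classification.

Core quantities per analysis cell:

* ``S_original`` — number of species actually recorded in the cell;
* ``S_potential`` — number of species predicted present by the ensemble
  models;
* ``S_r`` — richness of the union (each species counted once);
* completeness ``V_c = S_original / S_r`` and incompleteness
  ``V_inc = 1 - V_c``;
* weighted species richness ``WR = sum_i 1/c_i`` over the species in the
  cell, where ``c_i`` is the number of cells species *i* occupies
  (range-size rarity: narrow-ranged species weigh more);
* collection priority ``P = WR x V_inc`` — high where the cell is both
  under-surveyed and rich in narrow-ranged species.

Cells with ``S_r = 0`` carry no information about completeness and are
reported as missing (NaN), distinct from surveyed-and-complete cells with
``V_inc = 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridSystem

__all__ = [
    "cell_counts",
    "incompleteness",
    "weighted_richness",
    "collection_priority",
    "jenks_breaks",
    "assign_classes",
    "summarize_cells",
]

Cell = tuple[int, int]


def cell_counts(
    recorded: dict[str, set[Cell]],
    predicted: dict[str, set[Cell]],
    grid: GridSystem,
) -> pd.DataFrame:
    """Per-cell recorded, predicted, and union species counts.

    Returns a DataFrame indexed by flat cell id with columns cell_row,
    cell_col, S_original, S_potential, S_r (all grid cells included; cells
    with neither records nor predictions have all-zero counts).
    """
    s_orig = np.zeros(grid.n_cells, dtype=int)
    s_pot = np.zeros(grid.n_cells, dtype=int)
    s_r = np.zeros(grid.n_cells, dtype=int)
    all_species = set(recorded) | set(predicted)
    for sp in all_species:
        rec = recorded.get(sp, set())
        pred = predicted.get(sp, set())
        for (r, c) in rec:
            s_orig[r * grid.n_cols + c] += 1
        for (r, c) in pred:
            s_pot[r * grid.n_cols + c] += 1
        for (r, c) in rec | pred:
            s_r[r * grid.n_cols + c] += 1
    idx = np.arange(grid.n_cells)
    return pd.DataFrame({
        "cell_row": idx // grid.n_cols,
        "cell_col": idx % grid.n_cols,
        "S_original": s_orig,
        "S_potential": s_pot,
        "S_r": s_r,
    }, index=idx)


def incompleteness(S_original, S_r):
    """Completeness V_c = S_original / S_r and incompleteness V_inc = 1 - V_c.

    Works elementwise on scalars or arrays. Cells with ``S_r = 0`` yield NaN
    for both (no evidence, not completeness). Raises if any
    ``S_original > S_r``.
    """
    so = np.asarray(S_original, dtype=float)
    sr = np.asarray(S_r, dtype=float)
    if np.any(so > sr):
        raise ValueError("S_original cannot exceed S_r")
    if np.any(so < 0):
        raise ValueError("counts must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        v_c = np.where(sr > 0, so / np.where(sr > 0, sr, 1.0), np.nan)
    v_inc = 1.0 - v_c
    if np.ndim(S_original) == 0:
        return float(v_c), float(v_inc)
    return v_c, v_inc


def weighted_richness(species_cells: dict[str, set[Cell]]) -> dict[Cell, float]:
    """Range-size-weighted richness: WR(cell) = sum over resident species of
    1 / (number of cells that species occupies)."""
    wr: dict[Cell, float] = {}
    for sp, cells in species_cells.items():
        c_i = len(cells)
        if c_i == 0:
            continue
        share = 1.0 / c_i
        for cell in cells:
            wr[cell] = wr.get(cell, 0.0) + share
    return wr


def collection_priority(WR, V_inc):
    """Collection priority P = WR x V_inc (elementwise)."""
    wr = np.asarray(WR, dtype=float)
    vi = np.asarray(V_inc, dtype=float)
    if np.any(wr[np.isfinite(wr)] < 0):
        raise ValueError("WR must be nonnegative")
    finite = np.isfinite(vi)
    if np.any((vi[finite] < 0) | (vi[finite] > 1)):
        raise ValueError("V_inc must lie in [0, 1]")
    p = wr * vi
    return float(p) if np.ndim(WR) == 0 and np.ndim(V_inc) == 0 else p


def jenks_breaks(values, k: int) -> list[float]:
    """Exact Fisher–Jenks natural breaks.

    Partitions the sorted values into ``k`` contiguous classes minimising
    the total within-class sum of squared deviations, by dynamic
    programming (exact optimum, deterministic; ties resolved toward the
    earliest split). Returns the k-1 break points, each the maximum value
    of one of the first k-1 classes; classify with :func:`assign_classes`,
    whose intervals are open on the left and closed on the right
    (the last class absorbing everything above the final break).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of values n={n}")
    # prefix sums for O(1) segment SSD
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: int, j: int) -> float:
        # within-class SSD of v[i..j-1]
        m = j - i
        seg = s1[j] - s1[i]
        return (s2[j] - s2[i]) - seg * seg / m

    INF = np.inf
    # cost[j][c]: min total SSD of first j values in c classes
    cost = np.full((n + 1, k + 1), INF)
    split = np.zeros((n + 1, k + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, -1
            for i in range(c - 1, j):
                cand = cost[i][c - 1] + ssd(i, j)
                if cand < best - 1e-12:
                    best, best_i = cand, i
            cost[j][c] = best
            split[j][c] = best_i
    # backtrack class boundaries (indices of class starts)
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[j][c]
        bounds.append(j)
    bounds.reverse()  # [0, ..., n]
    return [float(v[b - 1]) for b in bounds[1:-1]]


def assign_classes(values, breaks: list[float]) -> np.ndarray:
    """Class index (0-based) of each value given Jenks break points.

    Class i covers (breaks[i-1], breaks[i]]; the last class is unbounded
    above. NaN maps to -1.
    """
    arr = np.asarray(values, dtype=float)
    out = np.searchsorted(np.asarray(breaks, dtype=float), arr, side="left")
    out = np.where(np.isnan(arr), -1, out)
    return out.astype(int)


def summarize_cells(
    recorded: dict[str, set[Cell]],
    predicted: dict[str, set[Cell]],
    grid: GridSystem,
    occupancy_basis: str = "union",
    n_priority_classes: int = 5,
) -> pd.DataFrame:
    """Full per-cell summary: counts, V_c, V_inc, WR, P, and Jenks class of P.

    ``occupancy_basis`` chooses the species-occupancy definition behind
    ``c_i`` in WR: "union" (recorded or predicted cells; keeps WR defined in
    unsurveyed cells) or "recorded".
    """
    if occupancy_basis not in {"union", "recorded"}:
        raise ValueError("occupancy_basis must be 'union' or 'recorded'")
    counts = cell_counts(recorded, predicted, grid)
    v_c, v_inc = incompleteness(counts["S_original"].to_numpy(), counts["S_r"].to_numpy())
    counts["V_c"] = v_c
    counts["V_inc"] = v_inc

    if occupancy_basis == "union":
        species_cells = {
            sp: recorded.get(sp, set()) | predicted.get(sp, set())
            for sp in set(recorded) | set(predicted)
        }
    else:
        species_cells = dict(recorded)
    wr_map = weighted_richness(species_cells)
    wr = np.zeros(grid.n_cells)
    for (r, c), val in wr_map.items():
        wr[r * grid.n_cols + c] = val
    counts["WR"] = wr
    counts["P"] = np.where(np.isnan(v_inc), np.nan, wr * np.nan_to_num(v_inc))

    p_valid = counts["P"].dropna()
    if p_valid.nunique() >= n_priority_classes:
        breaks = jenks_breaks(p_valid.to_numpy(), n_priority_classes)
        counts["jenks_class"] = assign_classes(counts["P"].to_numpy(), breaks)
    else:
        counts["jenks_class"] = -1
    return counts
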