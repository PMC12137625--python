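"""Aligned predictor rasters and the per-cell covariate table.

Holds the environmental layers used by the distribution models and the
per-cell explanatory covariates used by the driver analysis, together with
the standard transforms: the pairwise-correlation collinearity filter,
the log10(n+1) variance-stabilising transform, z-score standardisation,
and raster-to-analysis-cell zonal aggregation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSystem
from .gridio import read_ascii_grid, write_ascii_grid

__all__ = [
    "EnvStack",
    "CovariateTable",
    "correlation_filter",
    "log10p1",
    "standardize",
    "zonal_mean",
]

GROUPS = ("safety", "attractiveness", "accessibility")


@dataclass
class EnvStack:
    """An ordered set of co-registered raster layers with a validity mask."""

    grid: GridSystem
    layers: dict[str, np.ndarray]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = self.grid.shape
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError("mask shape must match the grid")
        for name, layer in self.layers.items():
            if layer.shape != shape:
                raise ValueError(f"layer '{name}' shape {layer.shape} != grid {shape}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Valid-cells x layers matrix (mask applied, row-major cell order)."""
        names = names or self.names
        m = self.mask.ravel()
        return np.column_stack([self.layers[n].ravel()[m] for n in names])

    def values_at(self, cells: list[tuple[int, int]], names: list[str] | None = None) -> np.ndarray:
        names = names or self.names
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        return np.column_stack([self.layers[n][rows, cols] for n in names])

    def valid_cells(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask)
        return list(zip(rows.tolist(), cols.tolist()))

    @classmethod
    def from_landscape(cls, landscape) -> "EnvStack":
        return cls(grid=landscape.grid, layers=dict(landscape.env_layers))

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, layer in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", layer,
                             cell_size=self.grid.cell_size, origin=self.grid.origin)

    @classmethod
    def read(cls, directory: str | Path, names: list[str] | None = None) -> "EnvStack":
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc")) if names is None \
            else [directory / f"{n}.asc" for n in names]
        if not paths:
            raise FileNotFoundError(f"no .asc layers found in {directory}")
        layers: dict[str, np.ndarray] = {}
        meta = None
        for p in paths:
            grid_arr, m = read_ascii_grid(p)
            layers[p.stem] = grid_arr
            meta = m
        shape = next(iter(layers.values())).shape
        grid = GridSystem(shape[0], shape[1], cell_size=meta["cellsize"],
                          origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)))
        mask = np.all([np.isfinite(v) for v in layers.values()], axis=0)
        return cls(grid=grid, layers=layers, mask=mask)


@dataclass
class CovariateTable:
    """Per-analysis-cell explanatory covariates with group membership.

    ``df`` is indexed by flat cell id (with cell_row / cell_col columns
    available on write); ``group_map`` assigns every covariate column to one
    of safety, attractiveness, accessibility.
    """

    df: pd.DataFrame
    group_map: dict[str, str]

    def __post_init__(self) -> None:
        cols = set(self.df.columns) - {"cell_row", "cell_col"}
        if set(self.group_map) != cols:
            raise ValueError("group_map must cover exactly the covariate columns")
        bad = set(self.group_map.values()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown covariate groups: {bad}")

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c in self.group_map]

    def by_group(self) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {}
        for g in GROUPS:
            cols = [c for c in self.covariate_names if self.group_map[c] == g]
            if cols:
                out[g] = self.df[cols]
        return out

    def write(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.df.to_csv(csv_path, index_label="cell_id")
        with open(csv_path.with_suffix(".groups.json"), "w") as fh:
            json.dump(self.group_map, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, csv_path: str | Path) -> "CovariateTable":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, index_col="cell_id")
        with open(csv_path.with_suffix(".groups.json")) as fh:
            group_map = json.load(fh)
        return cls(df=df, group_map=group_map)


def correlation_filter(
    data: pd.DataFrame | EnvStack,
    threshold: float = 0.8,
    priority_order: list[str] | None = None,
) -> list[str]:
    """Greedy collinearity filter: keep a variable iff its |Pearson r| with
    every already-kept variable is below ``threshold``.

    Variables are scanned in ``priority_order`` (default: input order), so
    the earlier of a correlated pair survives. Zero-variance variables are
    excluded with a warning (r undefined).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(data, EnvStack):
        table = pd.DataFrame(data.matrix(), columns=data.names)
    else:
        table = data
    if table.shape[1] < 2:
        raise ValueError("need at least two variables to filter")
    order = priority_order or list(table.columns)
    unknown = set(order) - set(table.columns)
    if unknown:
        raise KeyError(f"priority_order names unknown variables: {sorted(unknown)}")
    retained: list[str] = []
    for name in order:
        x = table[name].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"variable '{name}' has zero variance; excluded", stacklevel=2)
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(x, table[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


def log10p1(values):
    """Elementwise log10(value + 1); inputs must be nonnegative."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("log10p1 requires nonnegative inputs")
    out = np.log10(arr + 1.0)
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column to mean 0 and sample SD 1 (ddof=1)."""
    sd = table.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    return (table - table.mean()) / sd


def zonal_mean(stack: EnvStack, grid: GridSystem, layer: str) -> np.ndarray:
    """Mean of valid raster pixels per analysis cell.

    Pixels are assigned to the analysis cell containing their center (an
    area-weighted mean when pixel grids nest within analysis cells, which is
    the supported layout). Cells with no valid pixel are NaN.
    """
    if layer not in stack.layers:
        raise KeyError(f"unknown layer '{layer}'")
    values = stack.layers[layer]
    rg = stack.grid
    # pixel-center coordinates
    ys = rg.origin[1] + (np.arange(rg.n_rows) + 0.5) * rg.cell_size
    xs = rg.origin[0] + (np.arange(rg.n_cols) + 0.5) * rg.cell_size
    xx, yy = np.meshgrid(xs, ys)
    rows, cols, inside = grid.assign(xx.ravel(), yy.ravel())
    valid = inside & stack.mask.ravel() & np.isfinite(values.ravel())
    flat = rows[valid] * grid.n_cols + cols[valid]
    sums = np.bincount(flat, weights=values.ravel()[valid], minlength=grid.n_cells)
    counts = np.bincount(flat, minlength=grid.n_cells)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means.reshape(grid.n_rows, grid.n_cols)
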