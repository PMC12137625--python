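"""Pixel-level surface-water occurrence frequency and inundation extent.

From per-pixel observation stacks (how many screened satellite
observations each pixel has, and in how many of those it showed water),
computes the water-occurrence frequency, classifies pixels as permanent
(frequency strictly above 75%) or seasonal (25% to 75%, both ends
included) water bodies, and aggregates the inundation extent — seasonal
water area as a fraction of total water area — to analysis cells.
Pixels with frequency below 25% carry no water class (ephemeral water is
ignored). QA screening drops any observation whose cloud / shadow / snow
contamination confidence exceeds 0.66 (strictly).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridSystem

__all__ = [
    "pixel_frequency",
    "classify_water",
    "inundation_extent",
    "qa_filter",
    "WATER_NONE",
    "WATER_SEASONAL",
    "WATER_PERMANENT",
]

WATER_NONE = 0
WATER_SEASONAL = 1
WATER_PERMANENT = 2


def pixel_frequency(valid_count: np.ndarray, water_count: np.ndarray) -> np.ndarray:
    """Water-occurrence frequency = water / valid observations per pixel.

    Pixels with no valid observation are NaN (missing, not zero). Raises if
    any water count exceeds its valid count or any count is negative.
    """
    valid = np.asarray(valid_count, dtype=float)
    water = np.asarray(water_count, dtype=float)
    if valid.shape != water.shape:
        raise ValueError("count grids must share shape")
    if np.any(valid < 0) or np.any(water < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(water > valid):
        raise ValueError("water_count exceeds valid_count")
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(valid > 0, water / np.where(valid > 0, valid, 1.0), np.nan)
    return freq


def classify_water(frequency: np.ndarray, seasonal_low: float = 0.25,
                   permanent_low: float = 0.75) -> np.ndarray:
    """Classify pixels by water frequency.

    frequency > permanent_low -> permanent; seasonal_low <= frequency <=
    permanent_low -> seasonal (closed interval); below -> none. Missing
    (NaN) frequency stays missing (coded -1).
    """
    if not (0 < seasonal_low < permanent_low < 1):
        raise ValueError("require 0 < seasonal_low < permanent_low < 1")
    f = np.asarray(frequency, dtype=float)
    out = np.full(f.shape, WATER_NONE, dtype=int)
    out[(f >= seasonal_low) & (f <= permanent_low)] = WATER_SEASONAL
    out[f > permanent_low] = WATER_PERMANENT
    out[np.isnan(f)] = -1
    return out


def inundation_extent(water_class: np.ndarray, analysis_grid: GridSystem,
                      pixel_grid: GridSystem | None = None) -> np.ndarray:
    """Per-analysis-cell inundation extent.

    IE = seasonal pixels / (seasonal + permanent pixels) within the cell;
    cells containing no water pixel are NaN. ``pixel_grid`` describes the
    raster geometry (defaults to one pixel per analysis cell footprint,
    i.e. the class grid already at analysis resolution).
    """
    wc = np.asarray(water_class)
    if pixel_grid is None:
        pixel_grid = GridSystem(wc.shape[0], wc.shape[1],
                                cell_size=analysis_grid.cell_size
                                * analysis_grid.n_rows / wc.shape[0],
                                origin=analysis_grid.origin)
    if wc.shape != pixel_grid.shape:
        raise ValueError("water_class shape must match pixel_grid")
    ys = pixel_grid.origin[1] + (np.arange(pixel_grid.n_rows) + 0.5) * pixel_grid.cell_size
    xs = pixel_grid.origin[0] + (np.arange(pixel_grid.n_cols) + 0.5) * pixel_grid.cell_size
    xx, yy = np.meshgrid(xs, ys)
    rows, cols, inside = analysis_grid.assign(xx.ravel(), yy.ravel())
    flat_cls = wc.ravel()
    keep = inside & (flat_cls >= WATER_SEASONAL)
    flat = rows[keep] * analysis_grid.n_cols + cols[keep]
    seasonal = np.bincount(flat, weights=(flat_cls[keep] == WATER_SEASONAL).astype(float),
                           minlength=analysis_grid.n_cells)
    total = np.bincount(flat, minlength=analysis_grid.n_cells)
    with np.errstate(invalid="ignore"):
        ie = np.where(total > 0, seasonal / np.maximum(total, 1), np.nan)
    return ie.reshape(analysis_grid.n_rows, analysis_grid.n_cols)


def qa_filter(obs_flags, confidence: float = 0.66) -> np.ndarray:
    """Validity mask for observations given contaminant confidences.

    ``obs_flags`` is an observations x flags array (or DataFrame) of
    cloud/shadow/snow confidences in [0, 1]; an observation is valid iff no
    flag's confidence strictly exceeds ``confidence``.
    """
    if isinstance(obs_flags, pd.DataFrame):
        arr = obs_flags.to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(obs_flags, dtype=float))
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("flag confidences must lie in [0, 1]")
    return ~(arr > confidence).any(axis=1)
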