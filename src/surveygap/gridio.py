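"""Plain-text raster I/O (ESRI ASCII grid dialect).

Arrays in this package are oriented with row 0 at the *bottom* of the map
(matching :class:`surveygap.grids.GridSystem`); the ASCII format stores the
top row first, so reading and writing flip the row order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    cell_size: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    nodata: float = _NODATA,
) -> None:
    """Write a 2-D array (row 0 = bottom) as an ESRI ASCII grid. NaN -> nodata."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    out = np.where(np.isnan(grid), nodata, grid)
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {origin[0]}\n"
        f"yllcorner {origin[1]}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid.

    Returns ``(grid, meta)`` with the grid flipped to row-0-at-bottom
    orientation, nodata cells replaced by NaN, and ``meta`` holding
    ``cellsize``, ``xllcorner``, ``yllcorner``, ``nrows``, ``ncols``.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in meta:
            raise ValueError(f"ASCII grid header missing '{key}': {path}")
    body = np.loadtxt(lines[i:], dtype=float)
    body = np.atleast_2d(body)
    nrows, ncols = int(meta["nrows"]), int(meta["ncols"])
    if body.shape != (nrows, ncols):
        body = body.reshape(nrows, ncols)
    nodata = meta.get("nodata_value", _NODATA)
    grid = body[::-1].copy()
    grid[grid == nodata] = np.nan
    return grid, meta
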