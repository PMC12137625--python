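"""Equal-area analysis lattice.

All spatial bookkeeping in the package runs over a planar rectangular grid
of square cells. Cell ids are 0-based ``(row, col)`` pairs with row 0 at the
bottom edge (lowest y). Cell extents are half-open: a point on a cell's
right or top boundary belongs to the next cell, and a point on the grid's
outer right/top boundary falls outside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSystem"]


@dataclass(frozen=True)
class GridSystem:
    """A regular lattice of square cells on planar coordinates.

    Parameters
    ----------
    n_rows, n_cols
        Cell counts along y and x.
    cell_size
        Side length of a cell, in the units of the input coordinates
        (default 100, matching a 100 x 100 km analysis grid on an
        equal-area projection with km units).
    origin
        ``(x0, y0)`` of the grid's lower-left corner.
    crs_note
        Free-text reminder of the coordinate system the grid assumes.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_note: str = "planar equal-area, arbitrary units"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Cell id containing the point, or None if outside the grid."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((y - self.origin[1]) / self.cell_size))
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return (row, col)
        return None

    def assign(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised point-to-cell assignment.

        Returns ``(rows, cols, inside)`` where ``inside`` is a boolean mask of
        points falling within the grid; rows/cols are meaningful only where
        ``inside`` is True.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cols = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        rows = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        inside = (rows >= 0) & (rows < self.n_rows) & (cols >= 0) & (cols < self.n_cols)
        return rows, cols, inside

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (row + 0.5) * self.cell_size
        return (x, y)

    def flat_index(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.asarray(rows) * self.n_cols + np.asarray(cols)

    def all_cells(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]
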