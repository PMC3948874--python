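"""Toroidal resource grid with linear regrowth and clamped stocks.

Each prey class forages a separate resource layer by default; a layer is one
``ResourceGrid``: a ``height x width`` array of per-cell stocks that regrow by
``inflow_rate`` units per update up to ``max_per_cell``.  Coordinates are
0-based ``(x, y)`` with x increasing eastward and y increasing southward; the
grid wraps in both directions (torus), so there are no edge cells.
"""

from __future__ import annotations

import numpy as np


class ResourceGrid:
    """One resource layer.

    Parameters
    ----------
    width, height : int
        Grid dimensions in cells (immutable after construction).
    max_per_cell : float
        Stock ceiling per cell, in resource units.
    inflow_rate : float
        Regrowth per cell per update, in resource units.
    initial_stock : float
        Uniform starting stock, ``0 <= initial_stock <= max_per_cell``.
    stock : ndarray, optional
        Existing ``(height, width)`` array to wrap (shared memory); used by
        the world state to expose its layer stack as per-class grids.
    """

    def __init__(self, width: int, height: int, max_per_cell: float = 1.0,
                 inflow_rate: float = 0.01, initial_stock: float = 1.0,
                 stock: np.ndarray | None = None):
        if width < 1 or height < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {width}x{height}")
        if max_per_cell <= 0:
            raise ValueError("max_per_cell must be positive")
        if inflow_rate < 0:
            raise ValueError("inflow_rate must be >= 0")
        if not 0 <= initial_stock <= max_per_cell:
            raise ValueError(
                f"initial_stock {initial_stock} outside [0, {max_per_cell}]")
        self._width = int(width)
        self._height = int(height)
        self.max_per_cell = float(max_per_cell)
        self.inflow_rate = float(inflow_rate)
        if stock is None:
            self.stock = np.full((self._height, self._width), float(initial_stock))
        else:
            if stock.shape != (self._height, self._width):
                raise ValueError("provided stock array has wrong shape")
            self.stock = stock
            self.stock[:] = float(initial_stock)

    @property
    def width(self) -> int:
        return self._width

    @property
    def height(self) -> int:
        return self._height

    @property
    def n_cells(self) -> int:
        return self._width * self._height

    @property
    def total_stock(self) -> float:
        return float(self.stock.sum())

    def wrap(self, x: int, y: int) -> tuple[int, int]:
        """Map any integer coordinate onto the torus."""
        return x % self._width, y % self._height

    def replenish(self) -> None:
        """One update's regrowth: add ``inflow_rate`` everywhere, clamp at the
        per-cell maximum."""
        np.minimum(self.stock + self.inflow_rate, self.max_per_cell, out=self.stock)

    def harvest(self, x: int, y: int, requested: float) -> float:
        """Remove and return ``min(requested, stock)`` from cell ``(x, y)``.

        Raises ``IndexError`` for out-of-bounds coordinates (the torus wrap is
        a movement concern; direct cell addressing is bounds-checked).
        """
        if requested < 0:
            raise ValueError("requested amount must be >= 0")
        if not (0 <= x < self._width and 0 <= y < self._height):
            raise IndexError(f"cell ({x}, {y}) out of bounds for {self._width}x{self._height} grid")
        taken = min(requested, float(self.stock[y, x]))
        self.stock[y, x] -= taken
        return taken


def init_grid(width: int, height: int, max_per_cell: float = 1.0,
              inflow_rate: float = 0.01, initial_stock: float = 1.0) -> ResourceGrid:
    """Construct a resource layer with every cell at ``initial_stock``."""
    return ResourceGrid(width, height, max_per_cell, inflow_rate, initial_stock)
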