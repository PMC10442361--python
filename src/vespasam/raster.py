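"""Minimal georeferenced raster container with plain-text (ESRI ASCII grid) I/O.

Grids live in a projected coordinate system with units of kilometres. The
array is stored row-major with row 0 at the *top* (largest y), matching the
ASCII-grid convention. Cell (row, col) has its centre at::

    x = xll + (col + 0.5) * cell
    y = yll + (nrows - row - 0.5) * cell
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "GridMismatchError"]

NODATA_DEFAULT = -9999.0


class GridMismatchError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass
class RasterGrid:
    """A single-band gridded layer.

    Parameters
    ----------
    values : 2-D array, row 0 at the top (north).
    cell : cell edge length in km.
    xll, yll : coordinates of the lower-left corner of the grid, km.
    nodata : value marking missing cells in serialized form.
    """

    values: np.ndarray
    cell: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle, km."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cell,
            self.yll + self.nrows * self.cell,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) centre coordinates as 1-D arrays (per col / per row)."""
        x = self.xll + (np.arange(self.ncols) + 0.5) * self.cell
        y = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell
        return x, y

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Return 2-D meshes of cell-centre x and y, shaped like ``values``."""
        x, y = self.cell_centers()
        return np.meshgrid(x, y)

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.cell - other.cell) <= tol
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
        )

    def require_same_grid(self, other: "RasterGrid") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.values.shape}@{self.cell}km vs "
                f"{other.values.shape}@{other.cell}km"
            )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing point (x, y); raises if outside."""
        xmin, ymin, xmax, ymax = self.extent
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        col = min(int((x - self.xll) / self.cell), self.ncols - 1)
        row = min(int((self.yll + self.nrows * self.cell - y) / self.cell), self.nrows - 1)
        return row, col

    def sample(self, xs, ys) -> np.ndarray:
        """Nearest-cell values at point coordinates (vectorized)."""
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        cols = np.clip(((xs - self.xll) / self.cell).astype(int), 0, self.ncols - 1)
        ytop = self.yll + self.nrows * self.cell
        rows = np.clip(((ytop - ys) / self.cell).astype(int), 0, self.nrows - 1)
        return self.values[rows, cols]

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(np.asarray(values), self.cell, self.xll, self.yll, self.nodata)

    # -- I/O --------------------------------------------------------------
    def write_ascii(self, path: str | Path, fmt: str = "%.10g") -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        path = Path(path)
        vals = np.where(np.isfinite(self.values.astype(float)), self.values, self.nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.xll:.10g}\n"
            f"yllcorner {self.yll:.10g}\n"
            f"cellsize {self.cell:.10g}\n"
            f"NODATA_value {self.nodata:.10g}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt=fmt)

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        header: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        grid = cls(
            values,
            cell=header["cellsize"],
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            nodata=header.get("nodata_value", NODATA_DEFAULT),
        )
        grid.values = np.where(grid.values == grid.nodata, np.nan, grid.values)
        return grid


def write_stack(stack: dict[str, RasterGrid], out_dir: str | Path) -> list[Path]:
    """Write a named collection of layers as individual .asc files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, grid in stack.items():
        p = out_dir / f"{name}.asc"
        grid.write_ascii(p)
        paths.append(p)
    return paths
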