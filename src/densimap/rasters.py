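"""Plain-text raster I/O (ESRI ASCII grid).

Grids use cell-center registration: the value at array position [i, j]
belongs to the cell centered at ``(xll + (j + 0.5) * cell, yll + (i + 0.5) *
cell)`` with row 0 the southernmost row.  The on-disk ESRI format stores rows
north-to-south, so arrays are flipped on write and read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

NODATA = -9999.0


def write_ascii_grid(path: str | Path, grid: np.ndarray,
                     origin: tuple[float, float], cell_size: float,
                     nodata: float = NODATA) -> None:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    out = np.where(np.isfinite(grid), grid, nodata)
    header = (f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
              f"xllcorner {origin[0]!r}\nyllcorner {origin[1]!r}\n"
              f"cellsize {cell_size!r}\nNODATA_value {nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Return (grid, (xllcorner, yllcorner), cell_size); nodata becomes NaN."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)[::-1].copy()
    grid[grid == header["nodata_value"]] = np.nan
    return grid, (header["xllcorner"], header["yllcorner"]), header["cellsize"]
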