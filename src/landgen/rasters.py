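"""Single-band gridded rasters with ESRI ASCII grid I/O.

The grid convention follows the ASCII format: row 0 is the northernmost row,
``(xllcorner, yllcorner)`` anchor the lower-left corner, and cells are square
with side ``cell_size`` (map units, metres for the synthetic landscapes).
Nodata cells are carried as NaN in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster: 2-D float array plus georeferencing."""

    data: np.ndarray            # (nrows, ncols); NaN = nodata
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)   # (xllcorner, yllcorner)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean nodata mask (True where missing)."""
        return ~np.isfinite(self.data)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a cell center (row 0 = top/north)."""
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def snap(self, x: float, y: float) -> tuple[int, int]:
        """Nearest in-bounds non-nodata cell for a map coordinate.

        Ties and out-of-bounds points resolve by clipping then a row-major
        scan over candidate cells at increasing Chebyshev radius.
        """
        x0, y0 = self.origin
        col = int(np.clip(np.floor((x - x0) / self.cell_size), 0, self.ncols - 1))
        row = int(
            np.clip(
                self.nrows - 1 - np.floor((y - y0) / self.cell_size), 0, self.nrows - 1
            )
        )
        if np.isfinite(self.data[row, col]):
            return row, col
        # spiral out to the nearest valid cell, row-major within each ring
        for radius in range(1, max(self.nrows, self.ncols)):
            rows = range(max(0, row - radius), min(self.nrows, row + radius + 1))
            best = None
            for r in rows:
                for c in range(max(0, col - radius), min(self.ncols, col + radius + 1)):
                    if max(abs(r - row), abs(c - col)) != radius:
                        continue
                    if np.isfinite(self.data[r, c]):
                        if best is None:
                            best = (r, c)
            if best is not None:
                return best
        raise ValueError("raster has no valid cells to snap to")


def write_ascii_grid(grid: Grid, path) -> None:
    """Write an ESRI ASCII grid (.asc), NaN encoded as the nodata value."""
    data = np.where(np.isfinite(grid.data), grid.data, _NODATA)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {_NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")


def read_ascii_grid(path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrows},{ncols})")
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(np.isclose(data, nodata), np.nan, data)
    return Grid(
        data=data,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
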