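"""Minimal georeferenced raster container with ESRI ASCII grid text I/O.

A :class:`RasterGrid` is a 2-D cell grid on a planar (metre) coordinate
system: row 0 is the *northernmost* row, column 0 the westernmost column,
and ``origin`` is the (x, y) of the lower-left corner of the grid, following
the ESRI ASCII grid convention.  All layers of one landscape share shape,
pixel size and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid"]


@dataclass
class RasterGrid:
    """A single-band raster on a regular square-pixel grid.

    Parameters
    ----------
    data
        2-D array, row 0 = top (north).
    pixel_size
        Cell edge length in metres; must be positive.
    origin
        (x, y) of the lower-left corner in metres.
    nodata
        Sentinel for missing cells (used only on write/read).
    """

    data: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "RasterGrid") -> bool:
        """True if *other* shares shape, pixel size and origin."""
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell centre, each shaped like ``data``."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.pixel_size
        ys = y0 + (nrow - np.arange(nrow) - 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def rowcol_to_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates for (row, col) indices."""
        nrow, _ = self.shape
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = y0 + (nrow - np.asarray(row) - 0.5) * self.pixel_size
        return x, y

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Grid indices of the cell containing planar point (x, y)."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.pixel_size))
        row = int(nrow - 1 - np.floor((y - y0) / self.pixel_size))
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({x}, {y}) falls outside the raster")
        return row, col

    # ---- text I/O (ESRI ASCII grid) -------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (.asc), NaN cells as nodata."""
        nrow, ncol = self.shape
        out = np.array(self.data, dtype=float)
        out[~np.isfinite(out)] = self.nodata
        header = (
            f"ncols {ncol}\n"
            f"nrows {nrow}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.pixel_size:.6f}\n"
            f"NODATA_value {self.nodata:g}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        """Read an ESRI ASCII grid; nodata cells become NaN."""
        meta: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value",
                }:
                    meta[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = meta.get("nodata_value", -9999.0)
        data = np.where(data == nodata, np.nan, data)
        return cls(
            data=data,
            pixel_size=meta["cellsize"],
            origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
            nodata=nodata,
        )
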