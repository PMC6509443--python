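"""Georeferenced raster grids and ESRI ASCII grid I/O.

The package's raster container is deliberately minimal: a 2-D float array,
a NoData mask, a square cell size, and the (x, y) of the lower-left corner.
Row 0 is the northernmost row and cell (row, col) has its *center* at

    x = xllcorner + (col + 0.5) * cell_size
    y = yllcorner + (n_rows - row - 0.5) * cell_size

which matches the ESRI ASCII grid convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "RasterFormatError", "read_raster", "write_raster"]


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


@dataclass
class RasterGrid:
    """A single-band raster with NoData mask.

    Parameters
    ----------
    values
        2-D array of cell values. Entries under the mask are ignored.
    nodata_mask
        Boolean array of the same shape; True marks NoData cells.
    cell_size
        Edge length of the (square) cells in map units (metres).
    origin
        (x, y) of the lower-left corner of the grid.
    crs_label
        Free-text description of the coordinate system.
    """

    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite value in unmasked cell")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """Map coordinates (x, y) of cell centers."""
        nrows = self.shape[0]
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell whose center is nearest to (x, y)."""
        nrows = self.shape[0]
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(nrows - 1 - np.floor((y - self.origin[1]) / self.cell_size))
        row = min(max(row, 0), nrows - 1)
        col = min(max(col, 0), self.shape[1] - 1)
        return row, col

    def xy_grids(self):
        """(x, y) center coordinates for every cell, as two 2-D arrays."""
        rows, cols = np.indices(self.shape)
        return self.cell_center(rows, cols)

    def like(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """New grid sharing this grid's geometry."""
        if mask is None:
            mask = self.nodata_mask.copy()
        return replace(self, values=np.asarray(values, dtype=float), nodata_mask=mask)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.nodata_mask)


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid.

    NoData cells (per the ``NODATA_value`` header) are flagged in the mask and
    their stored value replaced by 0 so the array stays finite.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raise RasterFormatError(
            "GeoTIFF input is not supported; convert to ESRI ASCII grid"
        )
    header: dict[str, float] = {}
    nodata = None
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: bad header value on line {i + 1}: {line.strip()!r}"
                ) from exc
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
        else:
            data_start = i
            break
    else:
        data_start = len(lines)
    missing = [k for k in ("ncols", "nrows", "cellsize") if k not in header]
    if missing:
        raise RasterFormatError(f"{path}: missing header field(s) {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    tokens = " ".join(lines[data_start:]).split()
    try:
        flat = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric data token ({exc})") from exc
    if flat.size != nrows * ncols:
        raise RasterFormatError(
            f"{path}: expected {nrows * ncols} data values, found {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    if nodata is not None:
        mask = values == nodata
    else:
        mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return RasterGrid(
        values=values,
        nodata_mask=mask,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_raster(grid: RasterGrid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write ``grid`` as an ESRI ASCII grid readable by :func:`read_raster`."""
    unmasked = grid.values[~grid.nodata_mask]
    if not np.all(np.isfinite(unmasked)):
        raise ValueError("non-finite value in unmasked cell")
    if np.any(unmasked == nodata):
        raise ValueError(f"unmasked cell equals the NoData sentinel {nodata}")
    nrows, ncols = grid.shape
    out = np.where(grid.nodata_mask, nodata, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(grid.origin[0])!r}\n")
        fh.write(f"yllcorner {float(grid.origin[1])!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
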