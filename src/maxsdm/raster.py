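"""Gridded raster layers and stacks on a common geographic lat/lon grid.

The canonical on-disk format is the ESRI ASCII grid (``.asc``): a six-line
header (``ncols``, ``nrows``, ``xllcorner``/``xllcenter``,
``yllcorner``/``yllcenter``, ``cellsize``, ``NODATA_value``) followed by
row-major cell values, row 0 being the northernmost row.  Coordinates are
WGS84 degrees and cells are squares in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "RasterGrid",
    "RasterStack",
    "RasterFormatError",
    "read_esri_ascii",
    "write_esri_ascii",
]

DEFAULT_NODATA = -9999.0


class RasterFormatError(ValueError):
    """Raised when an ESRI ASCII grid file violates the format."""


@dataclass
class RasterGrid:
    """A single raster layer with its geotransform and nodata sentinel.

    Parameters
    ----------
    nrows, ncols : int
        Lattice shape; ``values`` row 0 is the northernmost row.
    xll, yll : float
        Longitude/latitude of the lower-left *corner* of the grid, degrees.
    cellsize : float
        Cell edge length in degrees (cells are square).
    nodata : float
        Sentinel marking missing cells.
    values : numpy.ndarray
        ``(nrows, ncols)`` float array; non-finite entries are coerced to
        ``nodata`` on construction.
    """

    nrows: int
    ncols: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = DEFAULT_NODATA
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")
        if self.values is None:
            self.values = np.full((self.nrows, self.ncols), self.nodata, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.nrows}, {self.ncols})"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            self.values = self.values.copy()
            self.values[bad] = self.nodata

    # -- derived geometry -------------------------------------------------
    @property
    def xur(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def yur(self) -> float:
        return self.yll + self.nrows * self.cellsize

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata."""
        return self.values != self.nodata

    def contains(self, lon: float, lat: float) -> bool:
        """Half-open bounding-box membership (right/upper edge excluded)."""
        return self.xll <= lon < self.xur and self.yll <= lat < self.yur

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing the point.

        Cell membership uses half-open intervals anchored at the lower-left
        corner: ``[xll + j*cellsize, xll + (j+1)*cellsize)`` in longitude and
        analogously in latitude, so a point on a shared edge belongs to the
        next (right/upper) cell.
        """
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside grid bounds")
        col = int(math.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(math.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        # floating-point guard at the very edge
        col = min(col, self.ncols - 1)
        row = max(row, 0)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and abs(self.xll - other.xll) <= tol
            and abs(self.yll - other.yll) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """A geometry-sharing copy holding new cell values."""
        return RasterGrid(
            nrows=self.nrows,
            ncols=self.ncols,
            xll=self.xll,
            yll=self.yll,
            cellsize=self.cellsize,
            nodata=self.nodata if nodata is None else nodata,
            values=np.asarray(values, dtype=float),
        )


class RasterStack:
    """An ordered, geometry-aligned collection of named raster layers.

    A cell is *valid* iff no layer holds nodata there.
    """

    def __init__(self, layers: Mapping[str, RasterGrid] | None = None):
        self._layers: dict[str, RasterGrid] = {}
        if layers:
            for name, grid in layers.items():
                self.add(name, grid)

    def add(self, name: str, grid: RasterGrid) -> None:
        if self._layers:
            ref = next(iter(self._layers.values()))
            if not grid.same_geometry(ref):
                raise ValueError(
                    f"layer {name!r} geometry does not match the stack"
                )
        self._layers[name] = grid

    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def reference(self) -> RasterGrid:
        if not self._layers:
            raise ValueError("empty stack")
        return next(iter(self._layers.values()))

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones((self.reference.nrows, self.reference.ncols), dtype=bool)
        for grid in self._layers.values():
            mask &= grid.valid_mask
        return mask

    def subset(self, names: list[str]) -> "RasterStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack({n: self._layers[n] for n in names})

    def to_matrix(self, names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (cells × layers) value matrix over jointly valid cells.

        Returns the matrix and the flat indices (into the row-major lattice)
        of the valid cells, in lattice order.
        """
        names = names or self.names
        mask = self.valid_mask()
        flat_idx = np.flatnonzero(mask.ravel())
        cols = [self._layers[n].values.ravel()[flat_idx] for n in names]
        return np.column_stack(cols) if cols else np.empty((0, 0)), flat_idx


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_esri_ascii(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid file into a :class:`RasterGrid`.

    Both the ``*corner`` and ``*center`` header dialects are accepted; a
    center origin is converted to the corner convention by subtracting half a
    cell.  Raises :class:`RasterFormatError` on a malformed header or a row
    whose length does not match ``ncols``.
    """
    path = Path(path)
    header: dict[str, float] = {}
    center_x = center_y = False
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                       "yllcenter", "cellsize", "nodata_value"):
                if len(parts) != 2:
                    raise RasterFormatError(f"malformed header line: {line!r}")
                value = float(parts[1])
                if key == "xllcenter":
                    key, center_x = "xllcorner", True
                elif key == "yllcenter":
                    key, center_y = "yllcorner", True
                header[key] = value
            else:
                # first data row
                rows.append(np.array(parts, dtype=float))
                break
        missing = [k for k in _HEADER_KEYS[:5] if k not in header]
        if missing:
            raise RasterFormatError(f"missing header key(s): {', '.join(missing)}")
        header.setdefault("nodata_value", DEFAULT_NODATA)
        for line in lines:
            parts = line.split()
            if parts:
                rows.append(np.array(parts, dtype=float))

    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if len(rows) != nrows:
        raise RasterFormatError(
            f"expected {nrows} data rows, found {len(rows)} in {path.name}"
        )
    for i, row in enumerate(rows):
        if row.size != ncols:
            raise RasterFormatError(
                f"row {i}: expected {ncols} values, found {row.size}"
            )
    cellsize = header["cellsize"]
    xll = header["xllcorner"] - (cellsize / 2 if center_x else 0.0)
    yll = header["yllcorner"] - (cellsize / 2 if center_y else 0.0)
    return RasterGrid(
        nrows=nrows,
        ncols=ncols,
        xll=xll,
        yll=yll,
        cellsize=cellsize,
        nodata=header["nodata_value"],
        values=np.vstack(rows),
    )


def write_esri_ascii(grid: RasterGrid, path: str | Path) -> Path:
    """Write a :class:`RasterGrid` as an ESRI ASCII grid (corner dialect).

    Round-trips bit-for-bit in header integers and to full ``repr`` precision
    in cell values.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {float(grid.xll)!r}\n")
        fh.write(f"yllcorner {float(grid.yll)!r}\n")
        fh.write(f"cellsize {float(grid.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


def read_stack(paths: Mapping[str, str | Path]) -> RasterStack:
    """Read several ``.asc`` files into an aligned stack, name → path."""
    return RasterStack({name: read_esri_ascii(p) for name, p in paths.items()})
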