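"""Regular lon/lat climate grids and the CSV-grid file dialect.

Grids are stored as dense 2-D arrays with row 0 the northernmost row and
column 0 the westernmost column.  Geometry follows the ESRI-ASCII
convention: ``xll``/``yll`` are the coordinates of the lower-left *corner*
of the lower-left cell, and every cell is ``cellsize`` degrees square.
Coordinates are decimal degrees (WGS84).

The CSV-grid dialect is a plain-text raster: six header lines
(``ncols``, ``nrows``, ``xll``, ``yll``, ``cellsize``, ``nodata``)
followed by ``nrows`` comma-separated rows, north to south.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ClimateGrid", "ClimateLayerSet", "read_csv_grid", "write_csv_grid"]

NODATA_DEFAULT = -9999.0


@dataclass
class ClimateGrid:
    """One climate variable on a regular lon/lat grid."""

    values: np.ndarray  # (nrows, ncols); row 0 = northernmost
    xll: float
    yll: float
    cellsize: float
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple[int, int, float, float, float]:
        return (self.nrows, self.ncols, self.xll, self.yll, self.cellsize)

    def same_geometry(self, other: "ClimateGrid") -> bool:
        a, b = self.geometry(), other.geometry()
        return a[:2] == b[:2] and np.allclose(a[2:], b[2:])

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every cell center, each (nrows, ncols)."""
        lon = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x1 = self.xll + self.ncols * self.cellsize
        y1 = self.yll + self.nrows * self.cellsize
        return (lon >= self.xll) & (lon <= x1) & (lat >= self.yll) & (lat <= y1)

    def interpolate(self, lon, lat) -> np.ndarray:
        """Bilinear interpolation at point coordinates (cell-center anchored).

        Points outside the grid extent raise ``ValueError``.  Points in the
        half-cell margin between the outermost centers and the grid edge are
        clamped to the edge centers.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.argwhere(~inside).ravel()[:5]
            raise ValueError(
                f"coordinates outside grid extent at indices {bad.tolist()} "
                f"(extent lon [{self.xll}, {self.xll + self.ncols * self.cellsize}], "
                f"lat [{self.yll}, {self.yll + self.nrows * self.cellsize}])"
            )
        # fractional column/row in cell-center coordinates
        fx = (lon - (self.xll + 0.5 * self.cellsize)) / self.cellsize
        fy = ((self.yll + (self.nrows - 0.5) * self.cellsize) - lat) / self.cellsize
        fx = np.clip(fx, 0.0, self.ncols - 1.0)
        fy = np.clip(fy, 0.0, self.nrows - 1.0)
        j0 = np.floor(fx).astype(int)
        i0 = np.floor(fy).astype(int)
        j1 = np.minimum(j0 + 1, self.ncols - 1)
        i1 = np.minimum(i0 + 1, self.nrows - 1)
        tx = fx - j0
        ty = fy - i0
        v = self.values
        out = (
            v[i0, j0] * (1 - tx) * (1 - ty)
            + v[i0, j1] * tx * (1 - ty)
            + v[i1, j0] * (1 - tx) * ty
            + v[i1, j1] * tx * ty
        )
        return out


@dataclass
class ClimateLayerSet:
    """Named climate variables sharing one grid geometry, tagged by scenario."""

    scenario: str
    layers: dict[str, ClimateGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not grids[0].same_geometry(g):
                raise ValueError("all layers in a set must share geometry")

    @property
    def variables(self) -> list[str]:
        return list(self.layers.keys())

    def __getitem__(self, var: str) -> ClimateGrid:
        return self.layers[var]

    def geometry_grid(self) -> ClimateGrid:
        return next(iter(self.layers.values()))

    def stack(self, variables: list[str] | None = None) -> np.ndarray:
        """(nrows, ncols, n_vars) array in the given variable order."""
        variables = variables or self.variables
        missing = [v for v in variables if v not in self.layers]
        if missing:
            raise KeyError(f"missing layers: {missing}")
        return np.stack([self.layers[v].values for v in variables], axis=-1)

    def extract(self, lon, lat, variables: list[str] | None = None) -> np.ndarray:
        """Per-point environmental vectors by bilinear interpolation."""
        variables = variables or self.variables
        return np.column_stack([self.layers[v].interpolate(lon, lat) for v in variables])


def write_csv_grid(grid: ClimateGrid, path: str | Path) -> None:
    path = Path(path)
    vals = np.where(grid.mask(), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols,{grid.ncols}\n")
        fh.write(f"nrows,{grid.nrows}\n")
        fh.write(f"xll,{grid.xll!r}\n")
        fh.write(f"yll,{grid.yll!r}\n")
        fh.write(f"cellsize,{grid.cellsize!r}\n")
        fh.write(f"nodata,{grid.nodata!r}\n")
        for row in vals:
            fh.write(",".join(repr(float(x)) for x in row) + "\n")


def read_csv_grid(path: str | Path) -> ClimateGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().strip().split(",")
            header[key] = float(val)
        vals = np.loadtxt(fh, delimiter=",", ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(f"grid body {vals.shape} does not match header ({nrows}, {ncols})")
    return ClimateGrid(
        values=vals,
        xll=header["xll"],
        yll=header["yll"],
        cellsize=header["cellsize"],
        nodata=header["nodata"],
    )
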