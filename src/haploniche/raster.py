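"""ESRI ASCII grid rasters and multi-layer environmental stacks.

Grids are unprojected WGS84 lat-lon with square cells; cell membership
uses half-open intervals [x, x + cellsize). NODATA cells carry a mask;
any declared NODATA value is accepted. Round-trips through write/read
are bit-identical for finite cells and the NODATA mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class EnvRaster:
    """Named co-registered environmental layers on one grid.

    layers maps variable name -> (n_rows, n_cols) float array, row 0 at
    the top (north) as in the .asc convention. The mask marks NODATA
    cells (True = missing) and is shared by all layers.
    """

    xllcorner: float
    yllcorner: float
    cellsize: float
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None
    nodata_value: float = -9999.0

    def __post_init__(self):
        shapes = {v.shape for v in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers disagree on grid shape: {shapes}")
        if self.layers and self.mask is None:
            self.mask = np.zeros(next(iter(self.layers.values())).shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing the points; row 0 is north."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        row_from_bottom = np.floor((lat - self.yllcorner) / self.cellsize).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_index(lon, lat)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        if self.mask is not None:
            inb = np.where(ok)
            ok2 = ok.copy()
            ok2[inb] = ~self.mask[row[inb], col[inb]]
            return ok2
        return ok

    def extract(self, lon, lat) -> np.ndarray:
        """Environment matrix (points x variables) at the given coordinates."""
        row, col = self.cell_index(lon, lat)
        if np.any(~self.contains(lon, lat)):
            bad = np.flatnonzero(~self.contains(lon, lat)).tolist()
            raise ValueError(f"points outside the raster or on NODATA cells: rows {bad}")
        return np.column_stack([self.layers[v][row, col] for v in self.layers])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of every cell center, row-major from the top."""
        cols = self.xllcorner + (np.arange(self.n_cols) + 0.5) * self.cellsize
        rows = self.yllcorner + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cellsize
        lon, lat = np.meshgrid(cols, rows)
        return lon, lat

    def env_matrix(self) -> np.ndarray:
        """Unmasked-cell environment matrix plus the flat indices of those cells."""
        flat_ok = ~self.mask.ravel()
        return np.column_stack([self.layers[v].ravel()[flat_ok] for v in self.layers])

    def unmasked_flat_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.mask.ravel())


def read_raster(path: str | Path, name: str | None = None) -> EnvRaster:
    """Read a single-layer ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing header field {req}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = np.concatenate(rows) if rows else np.empty(0)
    if data.size != nrows * ncols:
        raise ValueError(
            f"{path}: header promises {nrows * ncols} cells, found {data.size}")
    grid = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    mask = grid == nodata
    return EnvRaster(xllcorner=header["xllcorner"], yllcorner=header["yllcorner"],
                     cellsize=header["cellsize"],
                     layers={name or path.stem: grid}, mask=mask,
                     nodata_value=nodata)


def write_raster(raster: EnvRaster, path: str | Path, layer: str | None = None) -> None:
    """Write one layer of an EnvRaster as an ESRI ASCII grid."""
    layer = layer or raster.variable_names[0]
    grid = raster.layers[layer].astype(float).copy()
    grid[raster.mask] = raster.nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {float(raster.xllcorner)!r}\n")
        fh.write(f"yllcorner {float(raster.yllcorner)!r}\n")
        fh.write(f"cellsize {float(raster.cellsize)!r}\n")
        fh.write(f"NODATA_value {float(raster.nodata_value)!r}\n")
        for row in grid:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def stack_rasters(rasters: dict[str, EnvRaster]) -> EnvRaster:
    """Combine single-layer rasters into one stack; geometry must agree and
    the NODATA masks are unioned."""
    first = next(iter(rasters.values()))
    layers, mask = {}, np.zeros(first.shape, dtype=bool)
    for name, r in rasters.items():
        if (r.shape != first.shape or r.xllcorner != first.xllcorner
                or r.yllcorner != first.yllcorner or r.cellsize != first.cellsize):
            raise ValueError(f"raster {name} geometry differs from the stack")
        layers[name] = next(iter(r.layers.values()))
        mask |= r.mask
    return EnvRaster(first.xllcorner, first.yllcorner, first.cellsize,
                     layers=layers, mask=mask, nodata_value=first.nodata_value)
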