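"""Raster stacks on a geographic lon/lat grid, ESRI ASCII grid I/O.

Layers share a single grid geometry; cells where any layer is nodata are
masked in all layers (intersection mask). Values are held as float arrays
with NaN marking nodata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..errors import RasterError

__all__ = ["GridGeometry", "RasterStack", "read_ascii_grid", "write_ascii_grid",
           "read_raster_stack", "correlation_filter"]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridGeometry:
    n_rows: int
    n_cols: int
    xllcorner: float
    yllcorner: float
    cellsize: float

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; row 0 is the top row."""
        col = int(math.floor((lon - self.xllcorner) / self.cellsize))
        row_from_bottom = int(math.floor((lat - self.yllcorner) / self.cellsize))
        row = self.n_rows - 1 - row_from_bottom
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise RasterError(f"point ({lon}, {lat}) falls outside the grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.n_rows - row - 0.5) * self.cellsize
        return lon, lat

    def cell_area_km2(self, row: int) -> float:
        """Cell area with cosine-latitude weighting."""
        _, lat = self.cell_center(row, 0)
        side = self.cellsize * math.pi / 180.0 * EARTH_RADIUS_KM
        return side * side * math.cos(math.radians(lat))


@dataclass(frozen=True)
class RasterStack:
    geometry: GridGeometry
    layers: dict[str, np.ndarray]  # name -> (n_rows, n_cols) float, NaN=nodata

    def __post_init__(self):
        g = self.geometry
        for name, arr in self.layers.items():
            if arr.shape != (g.n_rows, g.n_cols):
                raise RasterError(
                    f"layer {name!r} shape {arr.shape} does not match grid "
                    f"({g.n_rows}, {g.n_cols})"
                )
        # harmonise nodata: a cell missing in any layer is missing in all
        mask = self.mask
        for arr in self.layers.values():
            arr[~mask] = np.nan

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask (True where every layer has data)."""
        m = np.ones((self.geometry.n_rows, self.geometry.n_cols), dtype=bool)
        for arr in self.layers.values():
            m &= ~np.isnan(arr)
        return m

    def valid_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of valid cells, row-major."""
        return np.argwhere(self.mask)

    def values_at(self, cells: np.ndarray, layer_names=None) -> np.ndarray:
        """(k, n_layers) environmental matrix at the given (row, col) cells."""
        names = layer_names or self.layer_names
        return np.column_stack(
            [self.layers[nm][cells[:, 0], cells[:, 1]] for nm in names]
        )

    def subset(self, layer_names: list[str]) -> "RasterStack":
        missing = [n for n in layer_names if n not in self.layers]
        if missing:
            raise RasterError(f"unknown layers: {missing}")
        return RasterStack(
            self.geometry, {n: self.layers[n].copy() for n in layer_names}
        )

    def cell_areas_km2(self) -> np.ndarray:
        g = self.geometry
        col = np.array([g.cell_area_km2(r) for r in range(g.n_rows)])
        return np.repeat(col[:, None], g.n_cols, axis=1)


def read_ascii_grid(path: str | Path) -> tuple[GridGeometry, np.ndarray, float]:
    """Parse one ESRI ASCII grid; returns (geometry, values, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise RasterError(f"{path}: missing header field {req!r}")
    nodata = header.get("nodata_value", -9999.0)
    values = np.concatenate(rows) if rows else np.array([])
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if values.size != nr * nc:
        raise RasterError(
            f"{path}: expected {nr * nc} values, found {values.size}"
        )
    arr = values.reshape(nr, nc)
    arr = np.where(arr == nodata, np.nan, arr)
    geom = GridGeometry(nr, nc, header["xllcorner"], header["yllcorner"],
                        header["cellsize"])
    return geom, arr, nodata


def write_ascii_grid(
    path: str | Path, geometry: GridGeometry, values: np.ndarray,
    nodata: float = -9999.0, fmt: str = "%.6g",
) -> None:
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {geometry.n_cols}\n")
        fh.write(f"nrows {geometry.n_rows}\n")
        fh.write(f"xllcorner {geometry.xllcorner!r}\n")
        fh.write(f"yllcorner {geometry.yllcorner!r}\n")
        fh.write(f"cellsize {geometry.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def read_raster_stack(paths: dict[str, str | Path]) -> RasterStack:
    """Read named ASCII-grid layers into a stack with harmonised nodata."""
    layers: dict[str, np.ndarray] = {}
    geom: GridGeometry | None = None
    for name, p in paths.items():
        g, arr, _ = read_ascii_grid(p)
        if geom is None:
            geom = g
        elif g != geom:
            raise RasterError(
                f"layer {name!r} geometry {g} does not match {geom}"
            )
        layers[name] = arr
    if geom is None:
        raise RasterError("no layers given")
    return RasterStack(geom, layers)


def correlation_filter(
    stack: RasterStack,
    candidates: list[str] | None = None,
    keep_list: list[str] | None = None,
    r_max: float = 0.8,
) -> list[str]:
    """Drop collinear layers until no pair exceeds |r| = r_max.

    Pearson correlations are computed over valid cells. Iteratively drops
    the variable with the largest number of over-threshold partners
    (keep_list members are never dropped; ties by name); layers in
    keep_list that remain mutually correlated are kept with a warning.
    """
    import warnings

    names = list(candidates or stack.layer_names)
    keep = set(keep_list or [])
    mask = stack.mask
    data = {n: stack.layers[n][mask] for n in names}
    selected = list(names)

    def corr(a: str, b: str) -> float:
        x, y = data[a], data[b]
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    while True:
        over: dict[str, int] = {n: 0 for n in selected}
        pairs = []
        for i, a in enumerate(selected):
            for b in selected[i + 1:]:
                if abs(corr(a, b)) > r_max:
                    over[a] += 1
                    over[b] += 1
                    pairs.append((a, b))
        droppable = [n for n in selected if over[n] > 0 and n not in keep]
        if not droppable:
            if pairs:
                warnings.warn(
                    f"keep_list layers remain correlated above {r_max}: {pairs}"
                )
            return selected
        droppable.sort(key=lambda n: (-over[n], n))
        selected.remove(droppable[0])
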