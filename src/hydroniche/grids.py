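"""Raster containers for co-registered bioclimatic layers.

A :class:`ClimateStack` holds the six hydrological layers (MAP, P_dry,
P_seas, AET, PET, AI) on one shared north-up lon/lat grid.  Layers are
read and written as ESRI ASCII grids, one file per variable, so stacks
round-trip through plain text.

Grid convention: the grid origin is the upper-left corner of cell
(row 0, col 0); cell intervals are half-open, so a point exactly on a
cell's western or northern edge belongs to that cell.  Units follow the
source conventions: precipitation and evapotranspiration in mm,
precipitation seasonality in %, and the aridity index stored as the
CGIAR-style scaled integer (MAP/PET x 10^4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

#: Layers stored in a stack, in canonical order.
VARIABLES: tuple[str, ...] = ("MAP", "P_dry", "P_seas", "AET", "PET", "AI")

#: The five univariate habitat indicators derived from a stack.
INDICATORS: tuple[str, ...] = ("MAP", "AI", "AET_PET", "P_dry", "P_seas")

UNITS: dict[str, str] = {
    "MAP": "mm",
    "P_dry": "mm",
    "P_seas": "%",
    "AET": "mm",
    "PET": "mm",
    "AI": "dimensionless (x 1e4)",
    "AET_PET": "dimensionless",
}

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """North-up lon/lat grid; origin is the upper-left corner."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("grid must have at least 2 rows and 2 columns")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) with half-open cell intervals.

        Returns float arrays before bounds checks; callers use
        :meth:`contains` to mask out-of-grid points.
        """
        col = np.floor((np.asarray(lon, float) - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat, float)) / self.cell_size).astype(int)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.origin_lon + (np.asarray(col, float) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row, float) + 0.5) * self.cell_size
        return lon, lat

    @property
    def lat_min(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size


@dataclass
class ClimateStack:
    """Co-registered single-band layers keyed by variable name."""

    geometry: GridGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    nodata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.geometry.n_rows, self.geometry.n_cols):
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} does not match grid "
                    f"({self.geometry.n_rows}, {self.geometry.n_cols})"
                )
            self.layers[name] = arr
            self.nodata.setdefault(name, DEFAULT_NODATA)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def mask(self, name: str) -> np.ndarray:
        """Boolean array, True where the layer holds valid data."""
        return self.layers[name] != self.nodata[name]

    # ------------------------------------------------------------------ I/O

    def write_dir(self, directory: str | Path) -> None:
        """Write every layer as ``<directory>/<name>.asc`` (ESRI ASCII)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.layers:
            write_ascii_grid(
                directory / f"{name}.asc", self.layers[name], self.geometry, self.nodata[name]
            )

    @classmethod
    def read_dir(cls, directory: str | Path, variables: tuple[str, ...] = VARIABLES) -> "ClimateStack":
        directory = Path(directory)
        layers: dict[str, np.ndarray] = {}
        nodata: dict[str, float] = {}
        geometry: GridGeometry | None = None
        for name in variables:
            path = directory / f"{name}.asc"
            if not path.exists():
                raise FileNotFoundError(f"missing layer file: {path}")
            arr, geom, nd = read_ascii_grid(path)
            if geometry is None:
                geometry = geom
            elif geom != geometry:
                raise ValueError(f"layer {name!r} geometry differs from the first layer")
            layers[name] = arr
            nodata[name] = nd
        assert geometry is not None
        return cls(geometry=geometry, layers=layers, nodata=nodata)


def write_ascii_grid(
    path: str | Path, data: np.ndarray, geometry: GridGeometry, nodata: float = DEFAULT_NODATA
) -> None:
    data = np.asarray(data, float)
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.origin_lon!r}\n"
        f"yllcorner {geometry.lat_min!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.17g")  # 17 significant digits: exact float round-trip


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    geom = GridGeometry(
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
        n_cols=n_cols,
        n_rows=n_rows,
    )
    data = np.atleast_2d(np.asarray(data, float))
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} does not match header")
    return data, geom, header["nodata_value"]
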