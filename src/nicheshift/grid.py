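"""Gridded-layer container and plain-text raster I/O.

All analyses run on a single declared equal-area grid (metres). Layers are
2-D float arrays with NaN as the nodata token; every layer in a stack shares
the grid. Rasters round-trip through ESRI ASCII grid files (one per layer)
with a JSON manifest naming the layers, so a stack is fully text-serializable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Registration of an equal-area raster grid.

    Origin (x0, y0) is the lower-left corner; rows index northward from the
    bottom (row 0 = southernmost), columns eastward. Units are metres.
    """

    nrows: int
    ncols: int
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xc, yc) of shape (nrows, ncols) with cell-center coords."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell_size
        xc, yc = np.meshgrid(xs, ys)
        return xc, yc

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of points; -1 where the point is outside the extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col


@dataclass
class PredictorStack:
    """Co-registered named environmental layers for one time period."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    period_label: str = ""
    features: dict = field(default_factory=dict)  # vector features (shapely), optional

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid shape {self.grid.shape}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(f"stack has no layer {name!r}") from None

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def add(self, name: str, arr: np.ndarray) -> None:
        if arr.shape != self.grid.shape:
            raise ValueError(f"layer {name!r} shape mismatch")
        self.layers[name] = np.asarray(arr, dtype=float)

    def copy(self) -> "PredictorStack":
        return PredictorStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            period_label=self.period_label,
            features=dict(self.features),
        )


def write_ascii_grid(path: str, grid: GridSpec, arr: np.ndarray) -> None:
    """Write one layer as an ESRI ASCII grid (rows written north-to-south)."""
    out = np.where(np.isnan(arr), NODATA, arr)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out[::-1], fmt="%.10g")


def read_ascii_grid(path: str) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)[::-1].copy()
    arr[arr == hdr["nodata_value"]] = np.nan
    grid = GridSpec(
        nrows=int(hdr["nrows"]),
        ncols=int(hdr["ncols"]),
        cell_size=hdr["cellsize"],
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
    )
    return grid, arr


def write_stack(stack: PredictorStack, directory: str) -> None:
    """Serialize a stack: one .asc per layer plus manifest.json."""
    os.makedirs(directory, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(os.path.join(directory, f"{name}.asc"), stack.grid, arr)
    manifest = {
        "period_label": stack.period_label,
        "layers": sorted(stack.layers),
        "grid": {
            "nrows": stack.grid.nrows,
            "ncols": stack.grid.ncols,
            "cell_size": stack.grid.cell_size,
            "x0": stack.grid.x0,
            "y0": stack.grid.y0,
        },
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_stack(directory: str) -> PredictorStack:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    g = manifest["grid"]
    grid = GridSpec(g["nrows"], g["ncols"], g["cell_size"], g["x0"], g["y0"])
    layers = {}
    for name in manifest["layers"]:
        _, arr = read_ascii_grid(os.path.join(directory, f"{name}.asc"))
        layers[name] = arr
    return PredictorStack(grid=grid, layers=layers, period_label=manifest["period_label"])
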