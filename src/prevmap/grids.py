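"""Regular-grid definitions, covariate stacks and plain-text raster I/O.

All coordinates live in a projected, km-based, equal-area system; distances
are Euclidean. Cells are ordered row-major from the grid origin (row 0 is the
southern edge), and cell membership uses half-open intervals
[edge, edge + cell_size) in both axes.

Rasters are serialized as ESRI ASCII grids (``.asc``), a plain-text format
readable by GDAL/QGIS/R; the CRS label travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridDefinition:
    """A regular raster grid in projected km coordinates.

    Cell centers are ``origin + (index + 0.5) * cell_size``; the extent is
    half-open so a point on the top/right outer edge is outside the grid.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_label: str = "local-km"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    @property
    def diameter(self) -> float:
        """Diagonal length of the grid footprint, in coordinate units."""
        xmin, ymin, xmax, ymax = self.extent
        return float(np.hypot(xmax - xmin, ymax - ymin))

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) cell centers in row-major order."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (rows + 0.5) * self.cell_size
        return np.column_stack([x, y])

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Row-major cell index containing each point (half-open cells).

        Raises ``ValueError`` naming the first offending point if any point
        falls outside the grid extent.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        cols = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        rows = np.floor((y - self.origin_y) / self.cell_size).astype(np.int64)
        bad = (cols < 0) | (cols >= self.n_cols) | (rows < 0) | (rows >= self.n_rows)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({x[i]:g}, {y[i]:g}) falls outside the grid extent {self.extent}"
            )
        return rows * self.n_cols + cols

    def to_2d(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values).reshape(self.n_rows, self.n_cols)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "cell_size": self.cell_size,
            "crs_label": self.crs_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridDefinition":
        return cls(**d)


def write_ascii_grid(path: str | Path, grid: GridDefinition, values: np.ndarray) -> None:
    """Write one surface (row-major, row 0 = south) as an ESRI ASCII grid."""
    arr = grid.to_2d(np.asarray(values, dtype=float)).copy()
    arr[~np.isfinite(arr)] = NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores the northernmost row first
        np.savetxt(fh, arr[::-1], fmt="%.10g")


def read_ascii_grid(path: str | Path, crs_label: str = "local-km") -> tuple[GridDefinition, np.ndarray]:
    """Read an ESRI ASCII grid; returns (grid, row-major values, NODATA as nan)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridDefinition(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        crs_label=crs_label,
    )
    arr = np.atleast_2d(data)[::-1].reshape(grid.n_rows, grid.n_cols)
    arr = arr.astype(float)
    arr[arr == header.get("nodata_value", NODATA)] = np.nan
    return grid, arr.ravel()


@dataclass
class CovariateStack:
    """Named gridded surfaces sharing one grid definition.

    ``values`` has shape (n_layers, n_cells), row-major per layer. Missing
    cells are NaN and propagate as an explicit mask, never silent zeros.
    """

    grid: GridDefinition
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.names), self.grid.n_cells):
            raise ValueError("values must have shape (n_layers, n_cells)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate layer names")

    @property
    def n_layers(self) -> int:
        return len(self.names)

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.values[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no covariate layer named {name!r}") from None

    def subset(self, names: list[str]) -> "CovariateStack":
        idx = [self.names.index(n) for n in names]
        return CovariateStack(self.grid, list(names), self.values[idx])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, vals in zip(self.names, self.values):
            write_ascii_grid(out / f"{name}.asc", self.grid, vals)
        meta = {"names": self.names, "grid": self.grid.to_dict()}
        (out / "stack.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "CovariateStack":
        src = Path(in_dir)
        meta = json.loads((src / "stack.json").read_text())
        grid = GridDefinition.from_dict(meta["grid"])
        layers = []
        for name in meta["names"]:
            g, vals = read_ascii_grid(src / f"{name}.asc", crs_label=grid.crs_label)
            if (g.n_rows, g.n_cols) != (grid.n_rows, grid.n_cols):
                raise ValueError(f"layer {name!r} does not match the stack grid")
            layers.append(vals)
        return cls(grid, meta["names"], np.array(layers))


@dataclass
class PopulationRaster:
    """Gridded population-at-risk counts (children under 2 per cell)."""

    grid: GridDefinition
    under2_count: np.ndarray

    def __post_init__(self) -> None:
        self.under2_count = np.asarray(self.under2_count, dtype=float)
        if self.under2_count.shape != (self.grid.n_cells,):
            raise ValueError("under2_count must be 1-D with one value per cell")
        if not np.all(np.isfinite(self.under2_count)):
            raise ValueError("population raster contains non-finite values")
        if np.any(self.under2_count < 0):
            raise ValueError("population raster contains negative values")

    @property
    def total(self) -> float:
        return float(self.under2_count.sum())

    def save(self, path: str | Path) -> None:
        write_ascii_grid(path, self.grid, self.under2_count)

    @classmethod
    def load(cls, path: str | Path, crs_label: str = "local-km") -> "PopulationRaster":
        grid, vals = read_ascii_grid(path, crs_label=crs_label)
        return cls(grid, vals)


def extract_at_points(stack: CovariateStack, points: np.ndarray) -> np.ndarray:
    """Covariate values of the cell containing each point.

    Parameters
    ----------
    points : (n, 2) array of (x, y) projected coordinates.

    Returns
    -------
    (n, n_layers) matrix, columns in ``stack.names`` order.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = stack.grid.cell_index(pts[:, 0], pts[:, 1])
    return stack.values[:, idx].T
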