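"""Planar raster geometry shared by every layer in an analysis.

All coordinates are planar kilometres in an abstract Cartesian frame:
the modifiable-areal-unit mechanics studied here do not depend on a
geodetic datum, so no CRS is attached.  Pixel ``(i, j)`` covers the
half-open box ``[x0 + j*cell, x0 + (j+1)*cell) x [y0 + i*cell,
y0 + (i+1)*cell)``; row 0 is the southernmost row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Origin, cell size and dimensions of a raster grid.

    Parameters
    ----------
    x0, y0 : float
        Coordinates (km) of the lower-left corner of pixel ``(0, 0)``.
    cell : float
        Cell side length in km (must be positive).
    nrows, ncols : int
        Grid dimensions (each at least 1).
    """

    x0: float
    y0: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.nrows}x{self.ncols}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def width(self) -> float:
        return self.ncols * self.cell

    @property
    def height(self) -> float:
        return self.nrows * self.cell

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        return (self.x0, self.y0, self.x0 + self.width, self.y0 + self.height)

    def cell_area(self) -> float:
        return self.cell * self.cell

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate arrays ``(X, Y)``, each of shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the half-open pixel containing (x, y)."""
        j = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        i = np.floor((np.asarray(y) - self.y0) / self.cell).astype(int)
        return i, j

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        xmin, ymin, xmax, ymax = self.bounds
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def to_dict(self) -> dict:
        return {
            "x0": self.x0,
            "y0": self.y0,
            "cell": self.cell,
            "nrows": self.nrows,
            "ncols": self.ncols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{k: d[k] for k in ("x0", "y0", "cell", "nrows", "ncols")})


@dataclass
class PredictorStack:
    """A named set of co-registered predictor rasters plus a suitability mask.

    ``layers`` maps layer name to a float array of shape ``spec.shape``.
    ``mask`` is a boolean array of the same shape; True marks pixels
    deemed suitable for the population (densities are computed per
    suitable km², and predictions are made on suitable pixels only).
    """

    spec: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.spec.shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {self.spec.shape}"
                )
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        elif self.mask.shape != self.spec.shape:
            raise ValueError(
                f"mask has shape {self.mask.shape}, expected {self.spec.shape}"
            )

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def with_mask(self, mask: np.ndarray) -> "PredictorStack":
        return PredictorStack(spec=self.spec, layers=dict(self.layers), mask=mask)

    def suitable_matrix(self) -> np.ndarray:
        """Predictor matrix of shape (n_suitable, n_layers), row-major pixel order."""
        return np.column_stack([self.layers[n][self.mask] for n in self.layer_names])

    def copy(self) -> "PredictorStack":
        return PredictorStack(
            spec=self.spec,
            layers={k: v.copy() for k, v in self.layers.items()},
            mask=None if self.mask is None else self.mask.copy(),
        )


def write_raster(path: str | Path, array: np.ndarray, spec: GridSpec,
                 nodata: float = NODATA) -> None:
    """Write a single-band raster as float32 TIFF with a JSON geometry sidecar.

    NaN values are encoded as ``nodata``.  The sidecar ``<path>.json``
    records the grid origin, cell size and the nodata value so the grid
    can be reconstructed exactly on read.
    """
    import tifffile

    path = Path(path)
    out = np.asarray(array, dtype=np.float32).copy()
    out[~np.isfinite(out)] = nodata
    tifffile.imwrite(path, out)
    sidecar = dict(spec.to_dict(), nodata=nodata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a raster written by :func:`write_raster`; nodata becomes NaN."""
    import tifffile

    path = Path(path)
    arr = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr[arr == meta["nodata"]] = np.nan
    return arr, GridSpec.from_dict(meta)
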