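"""Categorical habitat raster on a regular planar grid.

The raster is stored row-major with row 0 at the *bottom* (y increasing with
row index), in a projected metric CRS.  On disk it is an ESRI ASCII grid
(plain text, top row first) with a JSON sidecar mapping integer codes to
habitat-class labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HABITAT_CLASSES",
    "AGRICULTURAL_CLASSES",
    "HabitatMap",
    "read_ascii_grid",
]

HABITAT_CLASSES = ("grassland", "cereal", "maize", "other_agri", "non_agri")
AGRICULTURAL_CLASSES = ("grassland", "cereal", "maize", "other_agri")


@dataclass
class HabitatMap:
    """Single-band categorical raster with integer class codes.

    Attributes
    ----------
    x0, y0 : float
        Coordinates (m) of the lower-left corner of the grid.
    cell_size : float
        Cell edge length in meters; cells are square.
    grid : ndarray of int, shape (n_rows, n_cols)
        Class code per cell, row 0 at the bottom.
    classes : tuple of str
        Code ``k`` means ``classes[k]``.
    """

    x0: float
    y0: float
    cell_size: float
    grid: np.ndarray
    classes: tuple[str, ...] = HABITAT_CLASSES

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.min() < 0 or self.grid.max() >= len(self.classes):
            raise ValueError("grid contains codes outside the class table")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.n_cols * self.cell_size,
            self.y0 + self.n_rows * self.cell_size,
        )

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        return (
            (np.asarray(x) >= xmin)
            & (np.asarray(x) < xmax)
            & (np.asarray(y) >= ymin)
            & (np.asarray(y) < ymax)
        )

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell_size)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell_size)
        return row.astype(np.int64), col.astype(np.int64)

    def class_code_at(self, x, y) -> np.ndarray:
        """Class code of the cell containing each point (point-in-cell)."""
        if not np.all(self.contains(x, y)):
            raise ValueError("point(s) outside the raster footprint")
        row, col = self.cell_index(x, y)
        return self.grid[row, col]

    def class_at(self, x: float, y: float) -> str:
        return self.classes[int(self.class_code_at(x, y))]

    def class_proportions(self) -> dict[str, float]:
        counts = np.bincount(self.grid.ravel(), minlength=len(self.classes))
        total = counts.sum()
        return {c: counts[k] / total for k, c in enumerate(self.classes)}

    # --- plain-text persistence ------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write as ESRI ASCII grid plus ``<path>.classes.json`` sidecar."""
        path = Path(path)
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {self.x0}\n"
            f"yllcorner {self.y0}\n"
            f"cellsize {self.cell_size}\n"
            f"NODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.grid[::-1], fmt="%d")
        sidecar = path.with_suffix(path.suffix + ".classes.json")
        sidecar.write_text(json.dumps({"classes": list(self.classes)}))


def read_ascii_grid(path: str | Path) -> HabitatMap:
    """Read an ESRI ASCII grid written by :meth:`HabitatMap.write`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh, dtype=np.int16)
    grid = np.atleast_2d(grid)[::-1]
    sidecar = path.with_suffix(path.suffix + ".classes.json")
    classes = tuple(json.loads(sidecar.read_text())["classes"]) if sidecar.exists() else HABITAT_CLASSES
    return HabitatMap(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        grid=grid,
        classes=classes,
    )
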