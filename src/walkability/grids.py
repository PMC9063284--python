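"""Planar raster container and plain-text raster I/O.

All spatial layers live in an arbitrary planar metric coordinate frame
(units of metres).  A :class:`GridLayer` stores one surface on a regular
square grid; row 0 is the *southernmost* row and cells are addressed by
half-open intervals ``[x0 + j*cell, x0 + (j+1)*cell)`` so that a point on
a shared cell edge belongs to exactly one cell.

Rasters are serialized as ESRI ASCII grids (``.asc``), which store rows
north-to-south; readers/writers flip accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: recognised value semantics for a layer
SEMANTICS = ("count", "fraction", "density", "value", "category")


@dataclass
class GridLayer:
    """One gridded surface: origin at the lower-left corner, square cells.

    Parameters
    ----------
    origin
        ``(x0, y0)`` of the lower-left corner of the raster, in metres.
    cell_m
        Cell edge length in metres (> 0).
    values
        2-D array, shape ``(nrows, ncols)``; ``values[0, :]`` is the
        southernmost row.
    semantics
        What a cell value means: ``"count"`` (events per cell),
        ``"fraction"`` (area share in [0, 1]), ``"density"`` (per km^2),
        ``"value"`` (unconstrained real) or ``"category"`` (integer code).
    """

    origin: tuple[float, float]
    cell_m: float
    values: np.ndarray
    semantics: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not self.cell_m > 0:
            raise ValueError(f"cell_m must be positive, got {self.cell_m}")
        if self.semantics not in SEMANTICS:
            raise ValueError(f"unknown semantics {self.semantics!r}")
        finite = self.values[np.isfinite(self.values)]
        if self.semantics == "fraction":
            if finite.size and (finite.min() < 0 or finite.max() > 1 + 1e-12):
                raise ValueError("fraction layer must lie in [0, 1]")
        elif self.semantics in ("count", "density"):
            if finite.size and finite.min() < 0:
                raise ValueError(f"{self.semantics} layer must be non-negative")

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_m, y0 + self.nrows * self.cell_m)

    def cell_index(self, x, y):
        """Row/col of the cell owning point(s) ``(x, y)`` (half-open rule).

        Returns ``(row, col, inside)`` arrays; indices are only valid where
        ``inside`` is True.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_m).astype(int)
        row = np.floor((y - y0) / self.cell_m).astype(int)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return row, col, inside

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(cx, cy)`` of shape ``(nrows, ncols)`` with centre coords."""
        x0, y0 = self.origin
        cx = x0 + (np.arange(self.ncols) + 0.5) * self.cell_m
        cy = y0 + (np.arange(self.nrows) + 0.5) * self.cell_m
        return np.meshgrid(cx, cy)

    def like(self, values: np.ndarray, semantics: str | None = None) -> "GridLayer":
        """New layer on the same grid with different values."""
        return GridLayer(self.origin, self.cell_m, values,
                         semantics or self.semantics)


# -- ESRI ASCII grid I/O (text raster format) -----------------------------

def write_ascii_grid(layer: GridLayer, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a layer as an ESRI ASCII grid (rows north-to-south)."""
    path = Path(path)
    vals = np.flipud(np.asarray(layer.values, dtype=float).copy())
    vals[~np.isfinite(vals)] = nodata
    header = (
        f"ncols {layer.ncols}\n"
        f"nrows {layer.nrows}\n"
        f"xllcorner {layer.origin[0]:.6f}\n"
        f"yllcorner {layer.origin[1]:.6f}\n"
        f"cellsize {layer.cell_m:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, semantics: str = "value") -> GridLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                meta[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.array(rows, dtype=float)
    nodata = meta.get("nodata_value")
    if nodata is not None:
        vals[vals == nodata] = np.nan
    vals = np.flipud(vals)
    return GridLayer((meta["xllcorner"], meta["yllcorner"]), meta["cellsize"],
                     vals, semantics)
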