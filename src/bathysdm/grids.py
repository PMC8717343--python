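"""Regular single-band raster grids.

The :class:`GridSurface` is the package's common currency: DEMs, terrain
derivatives, distance surfaces and probability surfaces are all instances.
The grid convention is fixed once here:

* ``(origin_x, origin_y)`` is the *outer corner* of cell ``(0, 0)``;
  row 0 is the northernmost row, so y decreases with row index.
* Cell centres sit at ``origin_x + (col + 0.5) * cell`` and
  ``origin_y - (row + 0.5) * cell``.
* DEM values are stored as positive-down depths (metres), not negative
  elevations.

Persistence uses the ESRI ASCII grid format, a plain-text raster format
readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class GridSurface:
    """A single-band regular raster with nodata support."""

    origin_x: float
    origin_y: float
    cell: float
    values: np.ndarray  # (nrows, ncols), float
    nodata_mask: np.ndarray | None = None  # True where missing
    crs_label: str = "local-metres"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")
            self.nodata_mask = self.nodata_mask | ~np.isfinite(self.values)

    # -- geometry ----------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent_x(self) -> float:
        return self.ncols * self.cell

    @property
    def extent_y(self) -> float:
        return self.nrows * self.cell

    def x_centres(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell

    def y_centres(self) -> np.ndarray:
        """North to south, matching row order."""
        return self.origin_y - (np.arange(self.nrows) + 0.5) * self.cell

    def centre_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, shape (nrows, ncols)."""
        x, y = np.meshgrid(self.x_centres(), self.y_centres())
        return x, y

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "GridSurface":
        return GridSurface(self.origin_x, self.origin_y, self.cell,
                           np.array(values, dtype=float),
                           None if mask is None else np.array(mask, dtype=bool),
                           self.crs_label)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((x >= self.origin_x) & (x <= self.origin_x + self.extent_x)
                & (y <= self.origin_y) & (y >= self.origin_y - self.extent_y))

    # -- sampling ----------------------------------------------------------

    def nearest_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point, clipped to the grid."""
        col = np.clip(np.floor((np.asarray(x) - self.origin_x) / self.cell).astype(int),
                      0, self.ncols - 1)
        row = np.clip(np.floor((self.origin_y - np.asarray(y)) / self.cell).astype(int),
                      0, self.nrows - 1)
        return row, col

    def sample_nearest(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.nearest_index(x, y)
        out = self.values[row, col].astype(float)
        out = np.where(self.nodata_mask[row, col], np.nan, out)
        out = np.where(self.contains(x, y), out, np.nan)
        return out

    def sample_bilinear(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Bilinear interpolation at arbitrary points.

        Points outside the grid return NaN.  Within the outer half-cell ring
        (outside the convex hull of cell centres) the sample clamps to the
        edge centres, i.e. constant extrapolation.  If any of the four
        contributing cells is nodata, NaN propagates.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)

        u = (x - self.origin_x) / self.cell - 0.5  # fractional col
        v = (self.origin_y - y) / self.cell - 0.5  # fractional row
        u = np.clip(u, 0.0, self.ncols - 1.0)
        v = np.clip(v, 0.0, self.nrows - 1.0)
        c0 = np.clip(np.floor(u).astype(int), 0, max(self.ncols - 2, 0))
        r0 = np.clip(np.floor(v).astype(int), 0, max(self.nrows - 2, 0))
        c1 = np.minimum(c0 + 1, self.ncols - 1)
        r1 = np.minimum(r0 + 1, self.nrows - 1)
        fu = u - c0
        fv = v - r0

        z00 = self.values[r0, c0]
        z01 = self.values[r0, c1]
        z10 = self.values[r1, c0]
        z11 = self.values[r1, c1]
        bad = (self.nodata_mask[r0, c0] | self.nodata_mask[r0, c1]
               | self.nodata_mask[r1, c0] | self.nodata_mask[r1, c1])
        out = ((1 - fv) * ((1 - fu) * z00 + fu * z01)
               + fv * ((1 - fu) * z10 + fu * z11))
        out = np.where(bad | ~inside, np.nan, out)
        return out

    # -- I/O ---------------------------------------------------------------

    def to_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (nodata = -9999)."""
        vals = np.where(self.nodata_mask, NODATA, self.values)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.origin_x:.6f}\n"
            f"yllcorner {self.origin_y - self.extent_y:.6f}\n"
            f"cellsize {self.cell:.6f}\n"
            f"NODATA_value {NODATA:.1f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.6f")

    @classmethod
    def from_ascii(cls, path: str | Path, crs_label: str = "local-metres") -> "GridSurface":
        with open(path) as fh:
            header: dict[str, float] = {}
            while len(header) < 6:
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        nodata = header.get("nodata_value", NODATA)
        mask = vals == nodata
        vals = np.where(mask, np.nan, vals)
        cell = header["cellsize"]
        origin_y = header["yllcorner"] + header["nrows"] * cell
        return cls(header["xllcorner"], origin_y, cell, vals, mask, crs_label)


def check_coregistered(*grids: GridSurface, tol: float = 1e-6) -> None:
    """Raise if the grids do not share origin, cell size and shape."""
    ref = grids[0]
    for g in grids[1:]:
        if (abs(g.origin_x - ref.origin_x) > tol or abs(g.origin_y - ref.origin_y) > tol
                or abs(g.cell - ref.cell) > tol or g.values.shape != ref.values.shape):
            raise ValueError("grids are not co-registered")
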