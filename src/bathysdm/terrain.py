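"""Multi-scale terrain derivatives of a bathymetric DEM.

The DEM ladder follows common seafloor-characterisation practice: smooth
the native-resolution DEM once with a 5x5 Gaussian kernel (to suppress
interpolation noise, worst near overlapping transect edges), resample
bilinearly to each coarser analysis resolution, then compute eight 3x3
focal derivatives per resolution:

slope, northness (NS), eastness (WE)  -- Horn gradient on elevation;
SD, TRI, TPI, roughness               -- window variability metrics;
MNC                                   -- mean curvature of a local quadratic.

Depths are stored positive-down; derivatives that care about up/down
(slope aspect, curvature sign) are computed on elevation = -depth so that
"concave" means a depression and northness/eastness point downslope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GridSurface

VARIABLES = ("slope", "NS", "WE", "SD", "TRI", "TPI", "roughness", "MNC")


@dataclass
class TerrainStack:
    """Named terrain layers, keyed ``{variable}_{resolution:g}``.

    ``depth_{native}`` is always present; the eight derivatives appear once
    per analysis resolution.  All layers of one resolution are co-registered.
    """

    layers: dict[str, GridSurface]
    resolutions: list[float]
    native_cell: float
    source_label: str = "reference"

    @property
    def feature_names(self) -> list[str]:
        """Deterministic order: depth first, then variable-major, resolution-minor."""
        names = [f"depth_{self.native_cell:g}"]
        for var in VARIABLES:
            for res in self.resolutions:
                names.append(f"{var}_{res:g}")
        return [n for n in names if n in self.layers]

    def write(self, directory) -> None:
        """One ESRI ASCII grid per layer plus a JSON manifest."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, grid in self.layers.items():
            grid.to_ascii(directory / f"{name}.asc")
        manifest = {"source": self.source_label, "native_cell": self.native_cell,
                    "resolutions": self.resolutions, "layers": sorted(self.layers)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, directory) -> "TerrainStack":
        """Load a stack previously written with :meth:`write`."""
        import json
        from pathlib import Path

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        layers = {name: GridSurface.from_ascii(directory / f"{name}.asc")
                  for name in manifest["layers"]}
        return cls(layers, [float(r) for r in manifest["resolutions"]],
                   float(manifest["native_cell"]), manifest["source"])


def _masked_convolve(values: np.ndarray, valid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    num = ndimage.convolve(np.where(valid, values, 0.0), kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def gaussian_smooth(dem: GridSurface, sigma_cells: float = 1.0) -> GridSurface:
    """5x5 Gaussian smoothing (sigma = 1 cell by default).

    The kernel is renormalized over valid cells, so nodata holes and grid
    edges are averaged over what is available rather than bleeding nodata.
    """
    if dem.nrows < 5 or dem.ncols < 5:
        raise ValueError("DEM must be at least 5 x 5 for the smoothing kernel")
    ax = np.arange(5) - 2.0
    k1 = np.exp(-0.5 * (ax / sigma_cells) ** 2)
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    valid = ~dem.nodata_mask
    out = _masked_convolve(dem.values, valid, kernel)
    return dem.copy_with(np.where(valid, out, np.nan), ~valid)


def resample_bilinear(surface: GridSurface, new_cell: float) -> GridSurface:
    """Cell-centre aligned bilinear resampling to a new cell size.

    The output grid shares the origin and covers the same extent (the last
    partial cell is dropped).  Nodata propagates where any contributing
    source cell is nodata.
    """
    if new_cell <= 0:
        raise ValueError("new_cell must be positive")
    ncols = max(int(np.floor(surface.extent_x / new_cell + 1e-9)), 1)
    nrows = max(int(np.floor(surface.extent_y / new_cell + 1e-9)), 1)
    out = GridSurface(surface.origin_x, surface.origin_y, new_cell,
                      np.full((nrows, ncols), np.nan), crs_label=surface.crs_label)
    gx, gy = out.centre_mesh()
    vals = surface.sample_bilinear(gx.ravel(), gy.ravel()).reshape(nrows, ncols)
    return out.copy_with(vals)


def _windows(values: np.ndarray) -> np.ndarray:
    """All 3x3 windows as an (nrows-2, ncols-2, 9) array (z1..z9 row-major)."""
    w = np.lib.stride_tricks.sliding_window_view(values, (3, 3))
    return w.reshape(w.shape[0], w.shape[1], 9)


def _pad_nan(core: np.ndarray) -> np.ndarray:
    return np.pad(core, 1, mode="constant", constant_values=np.nan)


def horn_slope_aspect(dem: GridSurface) -> tuple[GridSurface, GridSurface, GridSurface]:
    """Horn (3x3, weighted) slope and aspect, returned as (slope, NS, WE).

    Computed on elevation = -depth.  Slope is in degrees; aspect is the
    downslope compass direction (0 = north, clockwise) and is returned as
    its circular-safe components northness NS = cos(aspect) and eastness
    WE = sin(aspect).  Flat cells (slope 0) take NS = WE = 0.  Border cells
    and cells with incomplete neighborhoods are nodata.
    """
    elev = np.where(dem.nodata_mask, np.nan, -dem.values)
    w = _windows(elev)
    g = dem.cell
    z1, z2, z3, z4, _, z6, z7, z8, z9 = (w[..., i] for i in range(9))
    p = ((z3 + 2 * z6 + z9) - (z1 + 2 * z4 + z7)) / (8 * g)  # d(elev)/dx (east)
    q = ((z1 + 2 * z2 + z3) - (z7 + 2 * z8 + z9)) / (8 * g)  # d(elev)/dy (north)
    grad = np.hypot(p, q)
    slope = np.degrees(np.arctan(grad))
    aspect = np.degrees(np.arctan2(-p, -q)) % 360.0  # downslope azimuth
    # gradients below 1e-12 are rounding residue of the smoothing stage, not slope
    sloped = grad > 1e-12
    ns = np.where(sloped, np.cos(np.radians(aspect)), 0.0)
    we = np.where(sloped, np.sin(np.radians(aspect)), 0.0)
    ns = np.where(np.isnan(slope), np.nan, ns)
    we = np.where(np.isnan(slope), np.nan, we)
    return (dem.copy_with(_pad_nan(slope)), dem.copy_with(_pad_nan(ns)),
            dem.copy_with(_pad_nan(we)))


def focal_stat(dem: GridSurface, metric: str) -> GridSurface:
    """3x3 window variability metrics on depth.

    SD        sample (n-1) standard deviation of the 9 values;
    TRI       mean |centre - neighbor| over the 8 neighbors;
    TPI       centre - mean of the 8 neighbors;
    roughness window max - min.
    """
    depth = np.where(dem.nodata_mask, np.nan, dem.values)
    w = _windows(depth)
    centre = w[..., 4]
    nbr = np.delete(w, 4, axis=-1)
    if metric == "SD":
        out = np.std(w, axis=-1, ddof=1)
    elif metric == "TRI":
        out = np.mean(np.abs(nbr - centre[..., None]), axis=-1)
    elif metric == "TPI":
        out = centre - np.mean(nbr, axis=-1)
    elif metric == "roughness":
        out = np.max(w, axis=-1) - np.min(w, axis=-1)
    else:
        raise ValueError(f"unknown focal metric {metric!r}")
    return dem.copy_with(_pad_nan(out))


def _quadratic_coeff_kernels(g: float) -> np.ndarray:
    """Least-squares kernels for z = ax^2+by^2+cxy+dx+ey+f on a 3x3 window."""
    xs = np.array([-g, 0.0, g])
    X = []
    for yy in (g, 0.0, -g):       # rows north to south
        for xx in xs:
            X.append([xx * xx, yy * yy, xx * yy, xx, yy, 1.0])
    return np.linalg.pinv(np.array(X))  # (6, 9)


def mean_curvature(dem: GridSurface) -> GridSurface:
    """Mean curvature MNC = -(a + b) of the local quadratic fit (units 1/m).

    Fitted to elevation = -depth, so depressions (concave terrain) give
    negative MNC and domes positive, matching the usual cartographic sign
    language.
    """
    elev = np.where(dem.nodata_mask, np.nan, -dem.values)
    w = _windows(elev)
    M = _quadratic_coeff_kernels(dem.cell)
    a = np.einsum("ijk,k->ij", w, M[0])
    b = np.einsum("ijk,k->ij", w, M[1])
    return dem.copy_with(_pad_nan(-(a + b)))


def build_stack(dem: GridSurface, resolutions: list[float],
                source_label: str = "reference") -> TerrainStack:
    """Smooth once at native resolution, resample, derive at every resolution.

    Produces ``depth_{native}`` plus the eight derivatives per resolution
    (9 layers for one resolution, 33 for four).  Resolutions must not be
    finer than the native cell.
    """
    if not resolutions:
        raise ValueError("at least one analysis resolution is required")
    for res in resolutions:
        if res < dem.cell - 1e-9:
            raise ValueError(f"resolution {res} m is finer than the native cell {dem.cell} m")
    smoothed = gaussian_smooth(dem)
    layers: dict[str, GridSurface] = {f"depth_{dem.cell:g}": smoothed}
    for res in resolutions:
        level = smoothed if abs(res - dem.cell) < 1e-9 else resample_bilinear(smoothed, res)
        slope, ns, we = horn_slope_aspect(level)
        layers[f"slope_{res:g}"] = slope
        layers[f"NS_{res:g}"] = ns
        layers[f"WE_{res:g}"] = we
        for metric in ("SD", "TRI", "TPI", "roughness"):
            layers[f"{metric}_{res:g}"] = focal_stat(level, metric)
        layers[f"MNC_{res:g}"] = mean_curvature(level)
    return TerrainStack(layers, list(resolutions), dem.cell, source_label)
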