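"""Agreement between an interpolated DEM and the reference DEM.

Interpolated surfaces are trustworthy near the survey lines and degrade in
the gaps, so agreement is reported both overall and within distance bands
from the track lines (default (0,100], (100,200], (200,300], (300,400] m,
half-open so a pixel exactly on a band edge falls in the nearer band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import stats

from .grids import GridSurface, check_coregistered

DEFAULT_BANDS = ((0.0, 100.0), (100.0, 200.0), (200.0, 300.0), (300.0, 400.0))


@dataclass
class BandComparison:
    """Paired-pixel statistics of one distance band (None when n < 3)."""

    band: tuple[float, float]
    n_pixels: int
    pearson_r: float | None
    r_p_value: float | None
    r2: float | None
    ols_slope: float | None
    ols_intercept: float | None


def distance_to_track(grid: GridSurface, track_lines) -> GridSurface:
    """Euclidean distance (m) from every cell centre to the nearest track line.

    ``track_lines`` is a sequence of ((x0, y0), (x1, y1)) segments or any
    shapely-compatible linestring coordinate sequences.
    """
    if not track_lines:
        raise ValueError("at least one track line is required")
    mls = shapely.MultiLineString([list(seg) for seg in track_lines])
    gx, gy = grid.centre_mesh()
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    d = shapely.distance(pts, mls).reshape(grid.values.shape)
    return grid.copy_with(d, np.zeros_like(d, dtype=bool))


def _paired(pred: GridSurface, ref: GridSurface, extra_mask: np.ndarray | None = None):
    check_coregistered(pred, ref)
    ok = ~pred.nodata_mask & ~ref.nodata_mask
    if extra_mask is not None:
        ok &= extra_mask
    return pred.values[ok], ref.values[ok]


def _stats(p: np.ndarray, r: np.ndarray):
    """Pearson r (with two-sided t-test p), OLS of reference on predicted, R^2."""
    if np.ptp(p) == 0 or np.ptp(r) == 0:
        return None, None, None, None, None
    pr = stats.pearsonr(p, r)
    ols = stats.linregress(p, r)
    return float(pr.statistic), float(pr.pvalue), float(ols.rvalue ** 2), \
        float(ols.slope), float(ols.intercept)


def band_compare(pred: GridSurface, ref: GridSurface, dist: GridSurface,
                 bands=DEFAULT_BANDS) -> list[BandComparison]:
    """Correlation/regression of predicted vs reference pixels per distance band."""
    check_coregistered(pred, ref, dist)
    out = []
    for lo, hi in bands:
        sel = (dist.values > lo) & (dist.values <= hi)
        p, r = _paired(pred, ref, sel)
        if p.size < 3:
            out.append(BandComparison((lo, hi), int(p.size), None, None, None, None, None))
            continue
        pearson_r, pval, r2, slope, intercept = _stats(p, r)
        out.append(BandComparison((lo, hi), int(p.size), pearson_r, pval, r2,
                                  slope, intercept))
    return out


def surface_compare(pred: GridSurface, ref: GridSurface
                    ) -> tuple[float, float, float, float]:
    """Whole-surface (r, R^2, rmse, bias) over jointly valid pixels.

    bias = mean(predicted - reference); a degenerate (constant) surface
    yields r = R^2 = NaN but rmse/bias are still reported.
    """
    p, r = _paired(pred, ref)
    if p.size == 0:
        raise ValueError("surfaces share no valid pixels")
    rmse = float(np.sqrt(np.mean((p - r) ** 2)))
    bias = float(np.mean(p - r))
    pearson_r, _, r2, _, _ = _stats(p, r)
    if pearson_r is None:
        pearson_r, r2 = float("nan"), float("nan")
    return pearson_r, r2, rmse, bias
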