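"""Empirical semivariograms and Gaussian variogram model fitting.

The semivariogram gamma(h) = E[(z(s) - z(s+h))^2] / 2 summarises spatial
autocorrelation.  The only theoretical model used in this package is the
Gaussian model in effective-range form,

    gamma(h) = c0 + c * (1 - exp(-3 (h/a)^2)),

so that the fitted ``a`` is the distance at which gamma reaches ~95% of the
sill (c0 + c), the convention under which survey-scale ranges of a few
hundred metres are usually reported.  Geometric anisotropy is expressed by
rotating lag vectors into the major-axis frame and stretching the minor
component by 1/ratio before evaluating the isotropic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

_GAMMA_FLOOR = 1e-12


@dataclass
class VariogramEmpirical:
    """Binned empirical semivariogram, optionally directional."""

    lag_centres: np.ndarray     # metres, increasing
    semivariance: np.ndarray    # m^2
    pair_counts: np.ndarray
    direction: float | str = "omnidirectional"  # degrees from north, or the label
    tolerance: float = 22.5     # degrees, half-width

    def __post_init__(self) -> None:
        self.lag_centres = np.asarray(self.lag_centres, dtype=float)
        self.semivariance = np.asarray(self.semivariance, dtype=float)
        self.pair_counts = np.asarray(self.pair_counts, dtype=int)
        if np.any(np.diff(self.lag_centres) <= 0):
            raise ValueError("lag centres must be increasing")
        if np.any(self.semivariance < 0) or np.any(self.pair_counts < 1):
            raise ValueError("invalid empirical variogram bin")


@dataclass
class VariogramModel:
    """Fitted Gaussian semivariogram with geometric anisotropy.

    ``anisotropy_angle`` is the azimuth (degrees clockwise from north) of the
    major axis; ``anisotropy_ratio`` = minor range / major range in (0, 1].
    ``range_a`` is the effective (95%-sill) range along the major axis.
    """

    nugget: float
    partial_sill: float
    range_a: float
    anisotropy_angle: float = 0.0
    anisotropy_ratio: float = 1.0
    model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be non-negative")
        if self.range_a <= 0:
            raise ValueError("range must be positive")
        if not (0 < self.anisotropy_ratio <= 1):
            raise ValueError("anisotropy ratio must be in (0, 1]")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def effective_distance(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Anisotropy-corrected lag length for lag vectors (dx east, dy north)."""
        theta = np.deg2rad(self.anisotropy_angle)
        h_major = dx * np.sin(theta) + dy * np.cos(theta)
        h_minor = dx * np.cos(theta) - dy * np.sin(theta)
        return np.hypot(h_major, h_minor / self.anisotropy_ratio)

    def gamma_iso(self, h: np.ndarray) -> np.ndarray:
        """gamma at isotropic (already anisotropy-corrected) lag h."""
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * (1.0 - np.exp(-3.0 * (h / self.range_a) ** 2))
        return np.where(h <= 0, self.nugget, g)

    def gamma(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        return self.gamma_iso(self.effective_distance(dx, dy))

    def covariance(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        return self.sill - self.gamma(dx, dy)


def empirical_variogram(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    lag_width: float,
    max_lag: float,
    directions: list[float] | None = None,
    tolerance: float = 22.5,
) -> list[VariogramEmpirical]:
    """Binned method-of-moments semivariogram estimate.

    gamma_hat(h) = sum over pairs in the bin of (z_i - z_j)^2 / (2 N(h)).

    The omnidirectional variogram is always first in the returned list;
    directional ones (pair azimuth within ``tolerance`` of the direction,
    modulo 180 degrees) follow in the order given.  Empty bins are dropped
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.size < 30 and x.size != 2:  # the 2-point case is allowed for didactic use
        if x.size < 30:
            warnings.warn(f"only {x.size} points for variogram estimation")
    if lag_width <= 0 or max_lag <= 0:
        raise ValueError("lag_width and max_lag must be positive")

    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(max_lag, output_type="ndarray")
    if pairs.size == 0:
        raise ValueError("no point pairs within max_lag")
    dx = x[pairs[:, 1]] - x[pairs[:, 0]]
    dy = y[pairs[:, 1]] - y[pairs[:, 0]]
    dist = np.hypot(dx, dy)
    sqdiff = (z[pairs[:, 1]] - z[pairs[:, 0]]) ** 2
    azimuth = np.rad2deg(np.arctan2(dx, dy)) % 180.0

    nbins = max(int(np.ceil(max_lag / lag_width)), 1)
    edges = np.arange(nbins + 1) * lag_width
    which = np.clip(np.digitize(dist, edges) - 1, 0, nbins - 1)

    def _binned(sel: np.ndarray, label: float | str) -> VariogramEmpirical | None:
        counts = np.bincount(which[sel], minlength=nbins)
        sums = np.bincount(which[sel], weights=sqdiff[sel], minlength=nbins)
        keep = counts > 0
        if keep.sum() == 0:
            warnings.warn(f"variogram direction {label}: no pairs in any bin")
            return None
        if keep.sum() < nbins:
            warnings.warn(f"variogram direction {label}: {nbins - keep.sum()} empty bins dropped")
        centres = (edges[:-1] + lag_width / 2.0)[keep]
        gamma = sums[keep] / (2.0 * counts[keep])
        return VariogramEmpirical(centres, gamma, counts[keep], label, tolerance)

    out: list[VariogramEmpirical] = []
    omni = _binned(np.ones(dist.size, dtype=bool), "omnidirectional")
    if omni is not None:
        out.append(omni)
    for d in directions or []:
        delta = np.abs((azimuth - d + 90.0) % 180.0 - 90.0)
        emp = _binned(delta <= tolerance, float(d))
        if emp is not None:
            out.append(emp)
    return out


class VariogramFitError(RuntimeError):
    """Fit failure carrying the last iterate and the bin table."""

    def __init__(self, message: str, last_params: tuple, emp: VariogramEmpirical):
        super().__init__(message)
        self.last_params = last_params
        self.empirical = emp


def _fit_single(emp: VariogramEmpirical,
                fixed_sills: tuple[float, float] | None = None
                ) -> tuple[float, float, float]:
    """WLS fit of (nugget, partial sill, range) to one empirical variogram.

    Cressie weights N(h)/gamma_model(h)^2, iterated implicitly by letting the
    residual depend on the model value.  With ``fixed_sills = (c0, c)`` only
    the range is fitted — used for directional fits, whose sparse bins
    cannot constrain three parameters.
    """
    h = emp.lag_centres
    g = emp.semivariance
    n = emp.pair_counts.astype(float)
    min_bins = 3 if fixed_sills is not None else 4
    if h.size < min_bins:
        raise ValueError(f"need at least {min_bins} usable bins to fit a variogram")

    g_max = max(g.max(), _GAMMA_FLOOR)
    # initial guess: no nugget, sill from the top bins, range where gamma
    # first reaches 95% of the sill
    sill0 = max(np.mean(g[-max(3, h.size // 4):]), _GAMMA_FLOOR)
    above = h[g >= 0.95 * sill0]
    a0 = float(above[0]) if above.size else float(h[-1])
    a_max = h[-1] * 3.0

    def model(c0: float, c: float, a: float) -> np.ndarray:
        gm = c0 + c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        return np.maximum(gm, 1e-6 * g_max)

    if fixed_sills is None:
        def residual(p: np.ndarray) -> np.ndarray:
            gm = model(*p)
            return np.sqrt(n) * (gm - g) / gm

        x0 = np.array([0.0, sill0, max(a0, h[0])])
        bounds = (np.array([0.0, 0.0, h[0] * 1e-3]),
                  np.array([np.inf, np.inf, a_max]))
    else:
        c0_fix, c_fix = fixed_sills

        def residual(p: np.ndarray) -> np.ndarray:
            gm = model(c0_fix, c_fix, p[0])
            return np.sqrt(n) * (gm - g) / gm

        x0 = np.array([max(a0, h[0])])
        bounds = (np.array([h[0] * 1e-3]), np.array([a_max]))

    res = least_squares(residual, x0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise VariogramFitError("variogram fit did not converge", tuple(res.x), emp)
    a = float(res.x[-1])
    if a > 0.99 * a_max:
        raise VariogramFitError("fitted range ran to the bound (no sill reached "
                                "within the lag span)", tuple(res.x), emp)
    if fixed_sills is not None:
        return fixed_sills[0], fixed_sills[1], a
    c0, c, _ = res.x
    return float(c0), float(c), a


def fit_variogram(emps: list[VariogramEmpirical], anisotropic: bool = False) -> VariogramModel:
    """Fit the Gaussian model; optionally estimate geometric anisotropy.

    The omnidirectional variogram (first entry or the one labelled so)
    provides nugget and sill.  With ``anisotropic=True``, the nugget and
    sill are held at the omnidirectional values and only the range is
    fitted per directional variogram (sparse directional bins cannot
    constrain three parameters); the direction with the largest fitted
    range becomes the major axis.  The minor range is taken from the
    fitted direction closest to perpendicular to the major axis, and
    ratio = minor / major, clipped to (0, 1].  Directions whose range fit
    fails or runs away are skipped with a warning.
    """
    if not emps:
        raise ValueError("no empirical variograms given")
    omni = next((e for e in emps if e.direction == "omnidirectional"), emps[0])
    c0, c, a = _fit_single(omni)

    angle, ratio = 0.0, 1.0
    if anisotropic:
        directional = [e for e in emps if e.direction != "omnidirectional"]
        if len(directional) < 2:
            raise ValueError("anisotropic fit needs at least two directional variograms")
        a, angle, ratio = _fit_anisotropy(directional, c0, c, a)
    return VariogramModel(c0, c, a, angle, ratio)


def _fit_anisotropy(directional: list[VariogramEmpirical], c0: float, c: float,
                    a_omni: float) -> tuple[float, float, float]:
    """Joint WLS fit of (major range, angle, ratio) over all directional bins.

    Every directional bin contributes: a lag of length h in direction phi
    has effective length h * sqrt(cos^2 d + (sin d / ratio)^2) with
    d = phi - angle.  Nugget and sill stay fixed at the omnidirectional
    values.  Multistart over the observed directions guards against the
    180-degree-periodic angle landscape.
    """
    h = np.concatenate([e.lag_centres for e in directional])
    g = np.concatenate([e.semivariance for e in directional])
    n = np.concatenate([e.pair_counts for e in directional]).astype(float)
    phi = np.concatenate([np.full(e.lag_centres.size, np.deg2rad(float(e.direction)))
                          for e in directional])
    h_max = h.max()
    g_floor = 1e-6 * max(g.max(), _GAMMA_FLOOR)

    # parameterize by (major range, angle, minor range): for geometric
    # anisotropy the omnidirectional range lies between the two, which rules
    # out the degenerate huge-range/sliver-ratio optima that saturated
    # directional bins otherwise admit
    a_mid = min(max(a_omni, h.min()), h_max * 2.0)

    def residual(p: np.ndarray) -> np.ndarray:
        a_maj, ang, a_min = p
        d = phi - ang
        heff = h * np.sqrt(np.cos(d) ** 2 + (np.sin(d) * a_maj / a_min) ** 2)
        gm = np.maximum(c0 + c * (1.0 - np.exp(-3.0 * (heff / a_maj) ** 2)), g_floor)
        return np.sqrt(n) * (gm - g) / gm

    bounds = (np.array([a_mid, -np.pi, 0.05 * a_mid]),
              np.array([max(2.0 * a_mid, a_mid + 1.0), 2.0 * np.pi, a_mid]))
    best = None
    for e in directional:
        for m0 in (1.0, 0.5):
            x0 = np.array([min(1.2 * a_mid, bounds[1][0]),
                           np.deg2rad(float(e.direction)), m0 * a_mid])
            res = least_squares(residual, x0, bounds=bounds,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
            if best is None or res.cost < best.cost:
                best = res
    a_maj, ang, a_min = best.x
    ratio = float(min(max(a_min / a_maj, 1e-6), 1.0))
    if a_maj > 0.99 * bounds[1][0] and ratio > 0.95:
        warnings.warn("anisotropic fit degenerate; "
                      "falling back to the omnidirectional model")
        return a_omni, 0.0, 1.0
    return float(a_maj), float(np.rad2deg(ang) % 180.0), ratio
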