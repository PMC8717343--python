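"""Surface interpolation from point soundings.

Three families of interpolators, all neighborhood-local and driven by a
k-d tree search, mirroring standard gridding practice for singlebeam
surveys:

* **IDW** — inverse distance weighting with configurable power;
* **RBF** — local radial basis function collocation with a linear
  polynomial part, either a completely regularized spline (CRS) or a
  multiquadric basis, with an optional ridge ("robustness") on the
  diagonal for smoothing;
* **kriging** — ordinary (OK) or universal kriging with first/second
  degree local detrending (UK1/UK2), using a fitted Gaussian variogram
  with optional geometric anisotropy.  Solved in semivariogram form
  [Gamma F; F' 0][lambda; mu] = [gamma0; f0], prediction variance
  sigma^2 = gamma0'lambda + f0'mu.

Model selection follows leave-one-out cross-validation: IDW/RBF configs
are ranked by LOOCV RMSE; kriging configs by |ASE - RMSE|, the calibration
gap between the average kriging standard error and the realized RMSE; the
overall winner across families is the lowest RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import exp1

from .grids import GridSurface
from .soundings import SoundingSet
from .variogram import (VariogramEmpirical, VariogramModel,  # noqa: F401 (re-export)
                        empirical_variogram as _empirical_variogram_xy,
                        fit_variogram)

EXACT_HIT = 1e-9      # metres: a query closer than this to a datum is "on" it
KRIGE_JITTER = 1e-10  # diagonal jitter; the Gaussian model is ill-conditioned

_FAMILIES = {"IDW": "IDW", "RBF_CRS": "RBF", "RBF_M": "RBF",
             "OK": "kriging", "UK1": "kriging", "UK2": "kriging"}
_TREND_DEGREE = {"OK": 0, "UK1": 1, "UK2": 2}


@dataclass
class InterpConfig:
    """One interpolator configuration (method + its parameters)."""

    method: str
    power: float = 2.0          # IDW
    n_neighbors: int = 50
    delta: float = 1.0          # RBF shape/smoothness parameter
    robustness: float = 0.0     # RBF diagonal ridge
    variogram: VariogramModel | None = None  # kriging

    def __post_init__(self) -> None:
        if self.method not in _FAMILIES:
            raise ValueError(f"unknown method {self.method!r}; one of {sorted(_FAMILIES)}")
        if self.method == "IDW" and self.power <= 0:
            raise ValueError("IDW power must be positive")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.family == "kriging":
            if self.variogram is None:
                raise ValueError("kriging requires a fitted variogram model")
            nb = _n_basis(self.trend_degree)
            if self.n_neighbors < nb + 2:
                raise ValueError(f"{self.method} needs at least {nb + 2} neighbors")
        if self.family == "RBF" and self.robustness < 0:
            raise ValueError("robustness must be non-negative")

    @property
    def family(self) -> str:
        return _FAMILIES[self.method]

    @property
    def trend_degree(self) -> int:
        return _TREND_DEGREE.get(self.method, 0)

    def label(self) -> str:
        bits = [self.method, f"k={self.n_neighbors}"]
        if self.method == "IDW":
            bits.append(f"p={self.power:g}")
        if self.family == "RBF":
            bits.append(f"delta={self.delta:g} ridge={self.robustness:g}")
        if self.family == "kriging" and self.variogram is not None:
            bits.append("aniso" if self.variogram.anisotropy_ratio < 1 else "iso")
        return " ".join(bits)


@dataclass
class CVReport:
    """Leave-one-out cross-validation outcome for one configuration."""

    config: InterpConfig
    residuals: np.ndarray         # predicted - observed, metres
    rmse: float
    ase: float | None             # kriging only
    selection_score: float

    @property
    def n(self) -> int:
        return self.residuals.size


def make_grid(bounds: tuple[float, float, float, float], cell: float,
              crs_label: str = "local-metres") -> GridSurface:
    """Empty grid template covering (x0, y0, x1, y1) at the given cell size."""
    x0, y0, x1, y1 = bounds
    ncols = max(int(np.ceil((x1 - x0) / cell)), 1)
    nrows = max(int(np.ceil((y1 - y0) / cell)), 1)
    return GridSurface(x0, y0 + nrows * cell, cell,
                       np.full((nrows, ncols), np.nan), crs_label=crs_label)


def detrended_depths(s: SoundingSet, degree: int = 1) -> np.ndarray:
    """OLS polynomial-trend residuals of the depths (degree 0, 1 or 2).

    Bathymetry with a shelf-scale ramp is not second-order stationary; the
    variogram of raw depths keeps climbing with the squared trend and hides
    the sill.  Removing a low-degree polynomial before variogram estimation
    is the standard pragmatic fix (the kriging predictor itself re-models
    the trend through its universal-kriging basis).
    """
    z = s.data["depth"].to_numpy()
    if degree == 0:
        return z - z.mean()
    x = s.data["x"].to_numpy()
    y = s.data["y"].to_numpy()
    sx, sy = max(x.std(), 1.0), max(y.std(), 1.0)
    u, v = (x - x.mean()) / sx, (y - y.mean()) / sy
    cols = [np.ones_like(u), u, v]
    if degree >= 2:
        cols += [u * u, v * v, u * v]
    A = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(A, z, rcond=None)
    return z - A @ beta


def empirical_variogram(s: SoundingSet, lag_width: float, max_lag: float,
                        directions: list[float] | None = None,
                        tolerance: float = 22.5,
                        detrend_degree: int = 0) -> list[VariogramEmpirical]:
    """Empirical variogram of a sounding set (omnidirectional first).

    ``detrend_degree > 0`` estimates the variogram on polynomial-trend
    residuals instead of raw depths; see :func:`detrended_depths`.
    """
    z = (detrended_depths(s, detrend_degree) if detrend_degree > 0
         else s.data["depth"].to_numpy())
    return _empirical_variogram_xy(s.data["x"].to_numpy(), s.data["y"].to_numpy(),
                                   z, lag_width, max_lag, directions, tolerance)


# -- batched local predictors ----------------------------------------------

def _n_basis(degree: int) -> int:
    return {0: 1, 1: 3, 2: 6}[degree]


def _poly_basis(u: np.ndarray, v: np.ndarray, degree: int) -> np.ndarray:
    """Monomials of locally centred/scaled coords; stacked on the last axis."""
    one = np.ones_like(u)
    if degree == 0:
        cols = [one]
    elif degree == 1:
        cols = [one, u, v]
    else:
        cols = [one, u, v, u * u, v * v, u * v]
    return np.stack(cols, axis=-1)


def _chunks(n: int, system: int) -> int:
    # keep batched system storage around ~100 MB
    return max(1, int(8e6 / max(system * system, 1)))


def _solve_batch(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched solve with least-squares fallback for singular items.

    ``numpy.linalg.solve`` raises if *any* matrix in the batch is singular,
    so failures are isolated by bisecting the batch; only the truly singular
    systems pay for a pseudo-inverse.  Returns (solutions, flagged).
    """
    flagged = np.zeros(A.shape[0], dtype=bool)
    try:
        return np.linalg.solve(A, b[..., None])[..., 0], flagged
    except np.linalg.LinAlgError:
        if A.shape[0] == 1:
            x = np.linalg.lstsq(A[0], b[0], rcond=None)[0][None, :]
            return x, np.ones(1, dtype=bool)
        half = A.shape[0] // 2
        x1, f1 = _solve_batch(A[:half], b[:half])
        x2, f2 = _solve_batch(A[half:], b[half:])
        return np.concatenate([x1, x2]), np.concatenate([f1, f2])


def _neighbor_query(tree: cKDTree, q: np.ndarray, k: int,
                    exclude_index: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """k nearest data points per query; optionally drop the query itself.

    ``exclude_index[i]`` is the index of the datum that *is* query i (LOOCV).
    """
    n = tree.n
    if exclude_index is None:
        k_eff = min(k, n)
        d, idx = tree.query(q, k=k_eff)
    else:
        k_eff = min(k + 1, n)
        d, idx = tree.query(q, k=k_eff)
        if k_eff == 1:
            raise ValueError("not enough points for leave-one-out")
        drop = idx == exclude_index[:, None]
        # if the self point was not in the list (ties), drop the last column
        drop[~drop.any(axis=1), -1] = True
        keep = ~drop
        # each row keeps k_eff - 1 entries
        idx = idx[keep].reshape(len(q), k_eff - 1)
        d = d[keep].reshape(len(q), k_eff - 1)
        k_eff -= 1
    if d.ndim == 1:
        d, idx = d[:, None], idx[:, None]
    return d, idx


def _idw_values(pts: np.ndarray, z: np.ndarray, tree: cKDTree, q: np.ndarray,
                power: float, k: int, exclude_index=None) -> np.ndarray:
    d, idx = _neighbor_query(tree, q, k, exclude_index)
    # log-domain weights, normalised by the nearest distance, stable for any power
    with np.errstate(divide="ignore"):
        logd = np.log(np.maximum(d, EXACT_HIT))
    w = np.exp(-power * (logd - logd.min(axis=1, keepdims=True)))
    pred = np.sum(w * z[idx], axis=1) / np.sum(w, axis=1)
    hit = d[:, 0] < EXACT_HIT
    if np.any(hit):
        pred[hit] = z[idx[hit, 0]]
    return pred


def _rbf_kernel(r: np.ndarray, basis: str, delta: float) -> np.ndarray:
    if basis == "M":
        return np.sqrt(r * r + delta * delta)
    if basis == "CRS":
        rho = (delta * r / 2.0) ** 2
        out = np.zeros_like(rho)
        pos = rho > 0
        out[pos] = -(np.log(rho[pos]) + exp1(rho[pos]) + np.euler_gamma)
        return out
    raise ValueError(f"unknown RBF basis {basis!r}")


def _rbf_values(pts: np.ndarray, z: np.ndarray, tree: cKDTree, q: np.ndarray,
                basis: str, delta: float, robustness: float, k: int,
                exclude_index=None) -> np.ndarray:
    d, idx = _neighbor_query(tree, q, k, exclude_index)
    m, ke = idx.shape
    if ke < 3:
        raise ValueError("RBF needs a local neighborhood of at least 3 points")
    npoly = 3
    pred = np.empty(m)
    step = _chunks(m, ke + npoly)
    for lo in range(0, m, step):
        hi = min(lo + step, m)
        sl = slice(lo, hi)
        local = pts[idx[sl]] - q[sl, None, :]          # (b, ke, 2)
        scale = np.maximum(np.abs(local).max(axis=(1, 2), keepdims=True), 1.0)
        u = local[..., 0] / scale[..., 0]
        v = local[..., 1] / scale[..., 0]
        r = np.sqrt(_pairwise_sq(local))
        phi = _rbf_kernel(r, basis, delta)
        if robustness > 0:
            # smoothing ridge, signed to match the basis's conditional
            # definiteness (multiquadric is conditionally negative definite)
            sign = -1.0 if basis == "M" else 1.0
            phi = phi + sign * robustness * np.eye(ke)
        P = _poly_basis(u, v, 1)                        # (b, ke, 3)
        b = hi - lo
        A = np.zeros((b, ke + npoly, ke + npoly))
        A[:, :ke, :ke] = phi
        A[:, :ke, ke:] = P
        A[:, ke:, :ke] = np.transpose(P, (0, 2, 1))
        rhs = np.concatenate([z[idx[sl]], np.zeros((b, npoly))], axis=1)
        sol, flagged = _solve_batch(A, rhs)
        lam, beta = sol[:, :ke], sol[:, ke:]
        phi0 = _rbf_kernel(d[sl], basis, delta)
        pred[sl] = np.sum(phi0 * lam, axis=1) + beta[:, 0]  # poly at query = (1,0,0)
        if flagged.any():
            warnings.warn(f"{int(flagged.sum())} singular local RBF systems "
                          "solved by least squares")
    if robustness == 0:
        hit = d[:, 0] < EXACT_HIT
        pred[hit] = z[idx[hit, 0]]
    return pred


def _pairwise_sq(local: np.ndarray) -> np.ndarray:
    """Batched pairwise squared distances of (b, k, 2) point sets.

    Uses the Gram-matrix identity with a BLAS batched matmul; avoids the
    (b, k, k, 2) broadcast temporary, which dominates runtime otherwise.
    """
    s = np.einsum("bki,bki->bk", local, local)
    r2 = s[:, :, None] + s[:, None, :] - 2.0 * (local @ local.transpose(0, 2, 1))
    return np.maximum(r2, 0.0, out=r2)


def _aniso_transform(vm: VariogramModel, local: np.ndarray) -> np.ndarray:
    """Rotate/scale lag coordinates so the variogram is isotropic in them."""
    theta = np.deg2rad(vm.anisotropy_angle)
    major = local[..., 0] * np.sin(theta) + local[..., 1] * np.cos(theta)
    minor = (local[..., 0] * np.cos(theta) - local[..., 1] * np.sin(theta)) \
        / vm.anisotropy_ratio
    return np.stack([major, minor], axis=-1)


def _gamma_from_sq(vm: VariogramModel, h2: np.ndarray) -> np.ndarray:
    """Gaussian semivariance from squared (anisotropy-corrected) lag."""
    return vm.nugget + vm.partial_sill * (1.0 - np.exp(-3.0 * h2 / vm.range_a ** 2))


def _krige_values(pts: np.ndarray, z: np.ndarray, tree: cKDTree, q: np.ndarray,
                  vm: VariogramModel, trend_degree: int, k: int,
                  exclude_index=None) -> tuple[np.ndarray, np.ndarray]:
    """Local kriging prediction and standard error at query points."""
    d, idx = _neighbor_query(tree, q, k, exclude_index)
    m, ke = idx.shape
    nb = _n_basis(trend_degree)
    if ke < nb + 2:
        raise ValueError("not enough neighbors for the kriging trend basis")
    pred = np.empty(m)
    se = np.empty(m)
    step = _chunks(m, ke + nb)
    diag = np.arange(ke)
    for lo in range(0, m, step):
        hi = min(lo + step, m)
        sl = slice(lo, hi)
        local = pts[idx[sl]] - q[sl, None, :]           # (b, ke, 2)
        iso = _aniso_transform(vm, local)
        G = _gamma_from_sq(vm, _pairwise_sq(iso))
        G[:, diag, diag] = 0.0  # gamma(x_i, x_i) = 0; the nugget acts off-diagonal
        g0 = _gamma_from_sq(vm, np.einsum("bki,bki->bk", iso, iso))
        scale = np.maximum(np.abs(local).max(axis=(1, 2), keepdims=True), 1.0)
        u = local[..., 0] / scale[..., 0]
        v = local[..., 1] / scale[..., 0]
        F = _poly_basis(u, v, trend_degree)             # (b, ke, nb)
        f0 = np.zeros((hi - lo, nb))
        f0[:, 0] = 1.0                                  # basis at the (centred) query
        b = hi - lo
        A = np.zeros((b, ke + nb, ke + nb))
        A[:, :ke, :ke] = G + KRIGE_JITTER * np.eye(ke)
        A[:, :ke, ke:] = F
        A[:, ke:, :ke] = np.transpose(F, (0, 2, 1))
        rhs = np.concatenate([g0, f0], axis=1)
        sol, flagged = _solve_batch(A, rhs)
        lam, mu = sol[:, :ke], sol[:, ke:]
        pred[sl] = np.sum(lam * z[idx[sl]], axis=1)
        var = np.sum(lam * g0, axis=1) + np.sum(mu * f0, axis=1)
        se[sl] = np.sqrt(np.maximum(var, 0.0))
        if flagged.any():
            warnings.warn(f"{int(flagged.sum())} singular kriging systems "
                          "solved by pseudo-inverse")
    if vm.nugget == 0:
        hit = d[:, 0] < EXACT_HIT
        pred[hit] = z[idx[hit, 0]]
        se[hit] = 0.0
    return pred, se


# -- public prediction API --------------------------------------------------

def _prep(s: SoundingSet) -> tuple[np.ndarray, np.ndarray, cKDTree]:
    pts = s.xy
    z = s.data["depth"].to_numpy()
    return pts, z, cKDTree(pts)


def _grid_queries(grid: GridSurface) -> np.ndarray:
    gx, gy = grid.centre_mesh()
    return np.column_stack([gx.ravel(), gy.ravel()])


def idw_predict(s: SoundingSet, grid: GridSurface, power: float = 2.0,
                n_neighbors: int = 50) -> GridSurface:
    """IDW surface on the template grid."""
    pts, z, tree = _prep(s)
    vals = _idw_values(pts, z, tree, _grid_queries(grid), power, n_neighbors)
    return grid.copy_with(vals.reshape(grid.values.shape))


def rbf_predict(s: SoundingSet, grid: GridSurface, basis: str = "M",
                delta: float = 1.0, robustness: float = 0.0,
                n_neighbors: int = 50) -> GridSurface:
    """Local RBF surface (basis "M" multiquadric or "CRS")."""
    pts, z, tree = _prep(s)
    vals = _rbf_values(pts, z, tree, _grid_queries(grid), basis, delta,
                       robustness, n_neighbors)
    return grid.copy_with(vals.reshape(grid.values.shape))


def krige_predict(s: SoundingSet, grid: GridSurface, vm: VariogramModel,
                  trend_degree: int = 0, n_neighbors: int = 100
                  ) -> tuple[GridSurface, GridSurface]:
    """Kriging prediction and standard-error surfaces on the template grid."""
    pts, z, tree = _prep(s)
    pred, se = _krige_values(pts, z, tree, _grid_queries(grid), vm,
                             trend_degree, n_neighbors)
    shape = grid.values.shape
    return grid.copy_with(pred.reshape(shape)), grid.copy_with(se.reshape(shape))


def predict_with_config(s: SoundingSet, grid: GridSurface, cfg: InterpConfig) -> GridSurface:
    """Dispatch a grid prediction for any configuration (kriging drops the SE)."""
    if cfg.method == "IDW":
        return idw_predict(s, grid, cfg.power, cfg.n_neighbors)
    if cfg.family == "RBF":
        basis = "CRS" if cfg.method == "RBF_CRS" else "M"
        return rbf_predict(s, grid, basis, cfg.delta, cfg.robustness, cfg.n_neighbors)
    return krige_predict(s, grid, cfg.variogram, cfg.trend_degree, cfg.n_neighbors)[0]


def loocv(s: SoundingSet, cfg: InterpConfig) -> CVReport:
    """Leave-one-out cross-validation of one configuration.

    Each point is predicted from all others; the variogram is *not* refitted
    per fold.  RMSE = root mean squared residual; for kriging, ASE is the
    mean kriging standard error at the held-out points and the selection
    score is |ASE - RMSE|; for IDW/RBF the selection score is the RMSE.
    """
    if len(s) < 10:
        raise ValueError("leave-one-out needs at least 10 points")
    pts, z, tree = _prep(s)
    self_idx = np.arange(len(s))
    ase = None
    if cfg.method == "IDW":
        pred = _idw_values(pts, z, tree, pts, cfg.power, cfg.n_neighbors, self_idx)
    elif cfg.family == "RBF":
        basis = "CRS" if cfg.method == "RBF_CRS" else "M"
        pred = _rbf_values(pts, z, tree, pts, basis, cfg.delta, cfg.robustness,
                           cfg.n_neighbors, self_idx)
    else:
        pred, se = _krige_values(pts, z, tree, pts, cfg.variogram,
                                 cfg.trend_degree, cfg.n_neighbors, self_idx)
        ase = float(np.mean(se))
    residuals = pred - z
    rmse = float(np.sqrt(np.mean(residuals ** 2)))
    score = abs(ase - rmse) if ase is not None else rmse
    return CVReport(cfg, residuals, rmse, ase, score)


def optimize_rbf(s: SoundingSet, basis: str, n_neighbors: int,
                 delta_grid: list[float], robustness_grid: list[float],
                 subsample: int = 2000, seed: int = 0) -> InterpConfig:
    """Grid-search (delta, robustness) by LOOCV RMSE.

    LOOCV runs on a random subsample of at most ``subsample`` points for
    speed (the subsample seed is recorded in the returned config's label
    via the provenance of the sounding set).  Ties prefer the smallest
    delta, then the smallest robustness.
    """
    if not delta_grid or not robustness_grid:
        raise ValueError("parameter grids must be non-empty")
    sub = s
    if len(s) > subsample:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(s), subsample, replace=False))
        sub = s.with_data(s.data.iloc[pick], "subsample", n=subsample, seed=seed)
    method = "RBF_CRS" if basis == "CRS" else "RBF_M"
    best: tuple[float, InterpConfig] | None = None
    for delta in sorted(delta_grid):
        for rob in sorted(robustness_grid):
            cfg = InterpConfig(method, n_neighbors=n_neighbors, delta=delta,
                               robustness=rob)
            rmse = loocv(sub, cfg).rmse
            # differences below 1e-9 m are numerical noise, not a better fit
            if best is None or rmse < best[0] - 1e-9:
                best = (rmse, cfg)
    return best[1]


def select_best(reports: list[CVReport]) -> list[CVReport]:
    """Rank configurations by the selection rules; best first.

    Within a family configurations are ordered by the family's selection
    score (LOOCV RMSE for IDW/RBF, |ASE - RMSE| for kriging).  Each family's
    top pick then competes across families on raw RMSE; the overall winner
    heads the returned list, followed by the other family winners by RMSE,
    then all remaining reports grouped by family in score order.
    """
    if not reports:
        raise ValueError("no cross-validation reports to rank")
    by_family: dict[str, list[CVReport]] = {}
    for r in reports:
        by_family.setdefault(r.config.family, []).append(r)
    for fam in by_family:
        by_family[fam].sort(key=lambda r: r.selection_score)
    winners = sorted((lst[0] for lst in by_family.values()), key=lambda r: r.rmse)
    rest = [r for lst in by_family.values() for r in lst[1:]]
    return winners + rest
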