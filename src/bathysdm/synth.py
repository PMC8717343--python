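"""Synthetic shelf seafloors, singlebeam-style surveys and species data.

This module generates data with the statistical structure a sparse-survey
interpolation study assumes, so the whole pipeline can be exercised and
verified at desk scale:

* a shelf DEM = across-shore depth ramp + anisotropic Gaussian random field
  (Gaussian covariance, geometric anisotropy, major axis parallel to the
  coast) + optional nugget noise, simulated exactly by FFT circulant
  embedding;
* a survey of parallel coast-wise transects with regular along-track
  sounding spacing, a sinusoidal tide, Gaussian depth noise and occasional
  spike errors;
* presence/absence records whose occurrence probability is a logistic
  function of depth (quadratic preference curve) and terrain variables.

Defaults mirror the study conditions the pipeline targets: a ~35 km x 5 km
shelf ramping from ~20 m at the coast to ~130 m offshore, 500 m transect
spacing and ~40 m along-track sounding spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import fft2, ifft2, next_fast_len

from .grids import GridSurface
from .soundings import SoundingSet, TideSeries


@dataclass
class SeafloorScenario:
    """Parameters of a synthetic shelf seafloor.

    ``trend`` is (depth at the coast in m, across-shore depth gradient in
    m per m); the coast is the northern edge of the grid and depth increases
    southwards.  ``anisotropy_angle`` is the azimuth (degrees from north) of
    the major continuity axis; 90 deg = east-west, i.e. coast-parallel.
    """

    extent_x: float = 35_000.0
    extent_y: float = 5_000.0
    cell: float = 25.0
    trend: tuple[float, float] = (20.0, 0.022)
    field_sill: float = 4.0          # m^2
    field_range_major: float = 600.0  # metres, effective (95% sill) range
    anisotropy_angle: float = 90.0
    anisotropy_ratio: float = 0.5
    nugget: float = 0.0              # m^2, iid cell noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_x <= 0 or self.extent_y <= 0 or self.cell <= 0:
            raise ValueError("extents and cell size must be positive")
        if self.field_range_major <= 0:
            raise ValueError("field_range_major must be positive")
        if not (0 < self.anisotropy_ratio <= 1):
            raise ValueError("anisotropy_ratio must be in (0, 1]")
        if self.field_sill < 0 or self.nugget < 0:
            raise ValueError("sill and nugget must be non-negative")


@dataclass
class SurveyDesign:
    """Acquisition geometry and error model of a singlebeam survey."""

    transect_spacing: float = 500.0   # metres, across-shore separation
    along_track_spacing: float = 40.0  # metres between depth records
    depth_noise_sd: float = 0.3       # metres
    spike_rate: float = 0.0           # probability a record is a spike
    spike_magnitude: float = 30.0     # metres, nominal spike size
    tide_amplitude: float = 1.0       # metres
    tide_period: float = 12.42        # hours (semi-diurnal)
    vessel_speed: float = 5.0         # m/s

    def __post_init__(self) -> None:
        if self.transect_spacing <= 0 or self.along_track_spacing <= 0:
            raise ValueError("spacings must be positive")
        if not (0 <= self.spike_rate < 1):
            raise ValueError("spike_rate must be in [0, 1)")
        if self.depth_noise_sd < 0:
            raise ValueError("depth_noise_sd must be non-negative")
        if self.vessel_speed <= 0:
            raise ValueError("vessel_speed must be positive")


@dataclass
class SpeciesParams:
    """Logistic occurrence model for one synthetic species.

    logit p = intercept - beta_depth * ((depth - depth_opt)/depth_tol)^2
              + sum_l beta_terrain[l] * standardized value of layer l.

    When ``target_prevalence`` is set the intercept is recalibrated (by
    bisection on the realized station set) so the expected prevalence
    matches it.
    """

    name: str
    intercept: float = 0.0
    depth_opt: float = 80.0
    depth_tol: float = 20.0
    beta_depth: float = 0.0
    beta_terrain: dict[str, float] = field(default_factory=dict)
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.depth_tol <= 0:
            raise ValueError("depth_tol must be positive")
        if self.target_prevalence is not None and not (0 < self.target_prevalence < 1):
            raise ValueError("target_prevalence must be in (0, 1)")


# -- Gaussian random field --------------------------------------------------

def _gaussian_random_field(nrows: int, ncols: int, cell: float, sill: float,
                           range_major: float, angle_deg: float, ratio: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Exact stationary GRF sample by circulant embedding.

    Covariance C(h) = sill * exp(-3 (h_eff / a)^2) with h_eff the
    anisotropy-corrected lag.  The torus is padded by ~2 ranges so the
    Gaussian covariance has decayed to ~1e-5 of the sill at the wrap-around,
    keeping the embedding (numerically) positive semi-definite.
    """
    if sill == 0:
        return np.zeros((nrows, ncols))
    pad = int(np.ceil(2.0 * range_major / cell)) + 1
    m = next_fast_len(nrows + pad)
    n = next_fast_len(ncols + pad)
    di = np.arange(m)
    dj = np.arange(n)
    di = np.where(di <= m // 2, di, di - m)[:, None].astype(float)
    dj = np.where(dj <= n // 2, dj, dj - n)[None, :].astype(float)
    dx = dj * cell
    dy = -di * cell  # row index increases southwards
    theta = np.deg2rad(angle_deg)
    h_major = dx * np.sin(theta) + dy * np.cos(theta)
    h_minor = dx * np.cos(theta) - dy * np.sin(theta)
    h_eff = np.hypot(h_major, h_minor / ratio)
    cov = sill * np.exp(-3.0 * (h_eff / range_major) ** 2)

    lam = fft2(cov).real
    lmax = lam.max()
    if lam.min() < -1e-3 * lmax:
        raise ValueError("covariance embedding is not positive semi-definite; "
                         "invalid scenario (range too long for the padded domain)")
    lam = np.clip(lam, 0.0, None)
    noise = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
    fld = np.real(ifft2(np.sqrt(lam) * noise)) * np.sqrt(m * n)
    return fld[:nrows, :ncols]


def generate_seafloor(scenario: SeafloorScenario) -> GridSurface:
    """Simulate a shelf DEM (depth positive down, metres).

    Deterministic for a fixed ``scenario.seed``: trend plane + GRF
    realization + independent nugget noise.
    """
    nrows = max(int(round(scenario.extent_y / scenario.cell)), 1)
    ncols = max(int(round(scenario.extent_x / scenario.cell)), 1)
    rng = np.random.default_rng(scenario.seed)

    # trend: coast at the north edge (row 0), deepening southwards
    y = (np.arange(nrows) + 0.5) * scenario.cell  # distance offshore of row centres
    depth0, grad = scenario.trend
    trend = depth0 + grad * y[:, None] * np.ones((1, ncols))

    fld = _gaussian_random_field(nrows, ncols, scenario.cell, scenario.field_sill,
                                 scenario.field_range_major, scenario.anisotropy_angle,
                                 scenario.anisotropy_ratio, rng)
    values = trend + fld
    if scenario.nugget > 0:
        values = values + rng.normal(0.0, np.sqrt(scenario.nugget), values.shape)
    return GridSurface(0.0, scenario.extent_y, scenario.cell, values)


# -- survey simulation ------------------------------------------------------

def sample_survey(dem: GridSurface, design: SurveyDesign, seed: int,
                  datum_offset: float = 0.30,
                  ) -> tuple[SoundingSet, TideSeries, list[tuple[tuple[float, float], tuple[float, float]]]]:
    """Simulate a transect survey over a DEM.

    Transects run parallel to the coast (east-west) and are spaced
    ``transect_spacing`` apart across-shore, edges inclusive; soundings are
    laid every ``along_track_spacing`` along track in serpentine order.
    Recorded raw depth = bilinear DEM depth + (tide - datum_offset) +
    Gaussian noise, with spike errors injected at ``spike_rate``.  The truth
    flag of each spike is kept in the ``spike`` column for validation use.

    Returns the raw soundings, the tide series needed to undo the tidal
    signal, and the track lines as ((x0, y0), (x1, y1)) segments.
    """
    rng = np.random.default_rng(seed)
    ex, ey = dem.extent_x, dem.extent_y
    if design.transect_spacing > ey:
        warnings.warn("transect spacing exceeds the across-shore extent; "
                      "producing a single transect")
    ys = np.arange(0.0, ey + 1e-9, design.transect_spacing)
    if ys.size == 0:
        ys = np.array([ey / 2.0])
    xs0 = np.arange(0.0, ex + 1e-9, design.along_track_spacing)

    rows = []
    tracks = []
    t = 0.0
    dt = design.along_track_spacing / design.vessel_speed
    turn_time = design.transect_spacing / design.vessel_speed
    for i, yv in enumerate(ys):
        xs = xs0 if i % 2 == 0 else xs0[::-1]  # serpentine
        tracks.append(((0.0, yv), (ex, yv)))
        times = t + np.arange(xs.size) * dt
        rows.append(pd.DataFrame({"x": xs, "y": yv, "t": times, "transect": i}))
        t = times[-1] + turn_time
    df = pd.concat(rows, ignore_index=True)

    period_s = design.tide_period * 3600.0
    phase = rng.uniform(0, 2 * np.pi)
    tide_t = np.arange(-600.0, df["t"].max() + 1200.0, 600.0)
    tide_h = design.tide_amplitude * np.sin(2 * np.pi * tide_t / period_s + phase)
    tide = TideSeries(tide_t, tide_h, datum_offset=datum_offset)

    true_depth = dem.sample_bilinear(df["x"].to_numpy(), df["y"].to_numpy())
    tide_at = design.tide_amplitude * np.sin(2 * np.pi * df["t"].to_numpy() / period_s + phase)
    noise = rng.normal(0.0, design.depth_noise_sd, len(df)) if design.depth_noise_sd > 0 else 0.0
    spikes = rng.random(len(df)) < design.spike_rate
    spike_amp = (rng.choice([-1.0, 1.0], len(df))
                 * design.spike_magnitude * rng.uniform(0.5, 1.5, len(df)))
    df["depth"] = true_depth + (tide_at - datum_offset) + noise + np.where(spikes, spike_amp, 0.0)
    df["spike"] = spikes.astype(int)

    s = SoundingSet(df[["x", "y", "t", "depth", "transect", "spike"]])
    s.provenance.append({"op": "sample_survey", "seed": seed,
                         "n": len(s), "n_transects": len(ys)})
    return s, tide, tracks


def tracks_to_wkt(tracks: list[tuple[tuple[float, float], tuple[float, float]]]) -> str:
    """Track segments as a WKT MULTILINESTRING (one text, GIS-readable)."""
    from shapely.geometry import MultiLineString

    return MultiLineString([list(seg) for seg in tracks]).wkt


# -- stations and species ---------------------------------------------------

def sample_stations(extent: tuple[float, float], n: int, min_separation: float,
                    seed: int, max_tries_per_point: int = 1000) -> np.ndarray:
    """Uniform station locations with a minimum separation (rejection sampling).

    Returns an (n, 2) array of (x, y).  Raises if the separation cannot be
    satisfied within the bounded number of retries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ex, ey = extent
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    tries = 0
    limit = max_tries_per_point * n
    while len(pts) < n:
        if tries >= limit:
            raise RuntimeError(
                f"could not place {n} stations with min separation {min_separation} m "
                f"in a {ex:.0f} x {ey:.0f} m extent after {limit} draws")
        cand = rng.uniform((0, 0), (ex, ey))
        tries += 1
        if min_separation > 0 and pts:
            d2 = np.min(np.sum((np.array(pts) - cand) ** 2, axis=1))
            if d2 < min_separation ** 2:
                continue
        pts.append(cand)
    return np.array(pts)


def simulate_species(stack, stations: np.ndarray, params: SpeciesParams, seed: int):
    """Draw Bernoulli presence/absence at stations from a logistic model.

    Depth enters through a quadratic preference curve centred at
    ``depth_opt`` with width ``depth_tol``; other terrain layers (named as
    in the stack, e.g. ``"TRI_75"``) enter linearly after standardization
    over the stations.  With ``target_prevalence`` set, the intercept is
    calibrated by bisection so the expected prevalence over these stations
    matches within 0.002.

    Returns a :class:`bathysdm.sdm.StationTable` with one presence column
    named after the species.
    """
    from .sdm import StationTable, extract_features

    table = extract_features(stack, stations)
    feats = table.features
    depth_name = next((c for c in feats.columns if c.startswith("depth")), None)
    if depth_name is None:
        raise ValueError("stack has no depth layer")
    depth = feats[depth_name].to_numpy()

    lin = -params.beta_depth * ((depth - params.depth_opt) / params.depth_tol) ** 2
    for layer, beta in params.beta_terrain.items():
        if layer not in feats.columns:
            raise KeyError(f"unknown terrain layer {layer!r}; available: "
                           f"{sorted(feats.columns)}")
        v = feats[layer].to_numpy()
        sd = v.std()
        lin = lin + beta * ((v - v.mean()) / sd if sd > 0 else 0.0)

    def expected_prev(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + lin)))))

    intercept = params.intercept
    if params.target_prevalence is not None:
        lo, hi = -30.0, 30.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if expected_prev(mid) < params.target_prevalence:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-9:
                break
        intercept = 0.5 * (lo + hi)
        if abs(expected_prev(intercept) - params.target_prevalence) > 0.02:
            raise RuntimeError("prevalence calibration failed")

    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + np.exp(-(intercept + lin)))
    presence = (rng.random(p.size) < p).astype(int)

    df = table.data.copy()
    df.insert(2, params.name, presence)
    return StationTable(df, table.feature_names, species=[params.name] + table.species)
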