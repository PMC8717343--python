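"""Shared fixtures: desk-scale synthetic scenarios and small sounding sets."""

import numpy as np
import pandas as pd
import pytest

from bathysdm.soundings import SoundingSet
from bathysdm.synth import (SeafloorScenario, SurveyDesign, generate_seafloor,
                            sample_survey)


def desk_scenario(seed: int, **overrides) -> SeafloorScenario:
    """Scaled-down shelf scenario used for repeated-seed simulations.

    Same structure as the full-size default (coast-parallel anisotropy,
    20 m + 0.022 m/m across-shore ramp, 500 m transect spacing downstream)
    but an 8 x 3 km extent at 25 m cells so multi-seed experiments stay fast.
    """
    params = dict(extent_x=8000.0, extent_y=3000.0, cell=25.0,
                  field_sill=4.0, field_range_major=600.0,
                  anisotropy_angle=90.0, anisotropy_ratio=0.5, seed=seed)
    params.update(overrides)
    return SeafloorScenario(**params)


def desk_survey(seed: int, noise_sd: float = 0.3, spike_rate: float = 0.0,
                scenario_overrides: dict | None = None):
    """(dem, raw soundings, tide, tracks) for one desk-scale seed."""
    dem = generate_seafloor(desk_scenario(seed, **(scenario_overrides or {})))
    design = SurveyDesign(depth_noise_sd=noise_sd, spike_rate=spike_rate)
    s, tide, tracks = sample_survey(dem, design, seed + 1000)
    return dem, s, tide, tracks


def scatter_soundings(n: int, seed: int, extent: float = 100.0,
                      values=None) -> SoundingSet:
    """Random scattered soundings, optionally with prescribed values."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, extent, (n, 2))
    z = values(pts) if callable(values) else (
        values if values is not None else rng.uniform(20, 80, n))
    return SoundingSet(pd.DataFrame(
        {"x": pts[:, 0], "y": pts[:, 1], "t": np.arange(n, dtype=float),
         "depth": np.asarray(z, dtype=float)}))


@pytest.fixture
def smooth_soundings() -> SoundingSet:
    """50 scattered points from a smooth analytic depth field."""
    return scatter_soundings(
        50, seed=7,
        values=lambda p: 50 + 10 * np.sin(p[:, 0] / 30) + p[:, 1] / 10)
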