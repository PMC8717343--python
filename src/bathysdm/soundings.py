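"""Point soundings and their quality control.

A :class:`SoundingSet` holds depth records (x, y, t, depth) from an
echo-sounder survey, depth positive down in metres.  QC follows the usual
singlebeam workflow: along-track block averaging to beat down ping noise,
tide correction to a common vertical datum, and automated despiking with a
running median/MAD filter in place of manual editing.  Every operation
appends to the set's provenance log so the applied order is auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SoundingSet:
    """Depth records with optional transect grouping.

    ``data`` columns: x, y (metres), t (seconds), depth (metres, positive
    down) and optionally ``transect`` (integer id).  Records are expected to
    be time-ordered within a transect.
    """

    data: pd.DataFrame
    crs_label: str = "local-metres"
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"x", "y", "t", "depth"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"sounding table missing columns: {sorted(missing)}")
        if not np.isfinite(self.data[["x", "y", "t"]].to_numpy()).all():
            raise ValueError("non-finite coordinates or times in sounding table")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy()

    def _log(self, op: str, **info) -> None:
        self.provenance.append({"op": op, **info})

    def with_data(self, data: pd.DataFrame, op: str, **info) -> "SoundingSet":
        out = SoundingSet(data.reset_index(drop=True), self.crs_label, list(self.provenance))
        out._log(op, **info)
        return out

    def groups(self):
        if "transect" in self.data.columns:
            return self.data.groupby("transect", sort=True)
        return [(0, self.data)]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        df = self.data.rename(columns={"depth": "depth_raw"})
        df.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=float))

    @classmethod
    def from_csv(cls, path: str | Path, crs_label: str = "local-metres") -> "SoundingSet":
        df = pd.read_csv(path)
        if "depth_raw" in df.columns:
            df = df.rename(columns={"depth_raw": "depth"})
        return cls(df, crs_label)


@dataclass
class TideSeries:
    """Tide heights (metres above chart datum) at increasing times.

    ``datum_offset`` converts chart datum to the working vertical datum
    (e.g. a height datum 0.30 m above chart datum gives offset 0.30).
    """

    t: np.ndarray
    height: np.ndarray
    datum_offset: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.height.shape:
            raise ValueError("tide series must be parallel 1-D arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("tide times must be strictly increasing")

    def height_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if t.min() < self.t[0] or t.max() > self.t[-1]:
            bad = int(np.argmax((t < self.t[0]) | (t > self.t[-1])))
            raise ValueError(
                f"sounding time {t.flat[bad]:.1f}s (record {bad}) outside tide span "
                f"[{self.t[0]:.1f}, {self.t[-1]:.1f}]")
        return np.interp(t, self.t, self.height)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "height": self.height}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, datum_offset: float = 0.0) -> "TideSeries":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["height"].to_numpy(), datum_offset)


@dataclass
class SoundingSummary:
    n: int
    min: float
    max: float
    mean: float
    skewness: float
    zero_variance: bool = False

    @property
    def transformation_advised(self) -> bool:
        """True when |skewness| exceeds 1, the usual pre-kriging threshold."""
        return abs(self.skewness) > 1.0


# -- operations ------------------------------------------------------------

def block_average(s: SoundingSet, k: int) -> SoundingSet:
    """Average consecutive non-overlapping blocks of ``k`` records per transect.

    Mirrors the noise-reduction step of averaging consecutive pings before
    depth picking, re-expressed in the depth domain.  A trailing remainder
    block is kept (averaged) if it holds at least k/2 records, else dropped.
    """
    if k < 1:
        raise ValueError("block size k must be >= 1")
    if k == 1:
        return s.with_data(s.data, "block_average", k=1)
    frames = []
    for tid, grp in s.groups():
        n = len(grp)
        nfull = n // k
        rem = n - nfull * k
        counts = [k] * nfull + ([rem] if rem >= k / 2 else [])
        idx = np.repeat(np.arange(len(counts)), counts)
        sub = grp.iloc[: idx.size]
        agg = sub.groupby(idx).mean(numeric_only=True)
        if "transect" in agg.columns:
            agg["transect"] = tid
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True) if frames else s.data.iloc[:0]
    return s.with_data(out, "block_average", k=k, n_in=len(s), n_out=len(out))


def tide_correct(s: SoundingSet, tide: TideSeries) -> SoundingSet:
    """Reduce raw depths to the working vertical datum.

    corrected = raw - (tide height at t - datum_offset).  Raises if any
    sounding time falls outside the tide series span (naming the record).
    """
    corr = tide.height_at(s.data["t"].to_numpy()) - tide.datum_offset
    out = s.data.copy()
    out["depth"] = out["depth"] - corr
    return s.with_data(out, "tide_correct", datum_offset=tide.datum_offset)


def despike(s: SoundingSet, window: int = 5, threshold_factor: float = 6.0) -> SoundingSet:
    """Remove outliers against a running median, per transect.

    A record is dropped when |depth - running median(window)| exceeds
    ``threshold_factor`` times a robust per-transect noise scale (floored at
    0.01 m), and any non-positive depth is dropped outright.  The scale is
    the MAD of first differences of the depth series, normalised to a
    Gaussian sigma (x1.4826 / sqrt(2)): differencing cancels the smooth
    along-track seafloor signal, and the median makes the estimate immune
    to the spikes being hunted.  A robust, parameter-light stand-in for
    manual sounding editing.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    keep_parts = []
    for _, grp in s.groups():
        depth = grp["depth"]
        med = depth.rolling(window, center=True, min_periods=1).median()
        resid = depth - med
        diffs = depth.diff().dropna()
        if len(diffs):
            sigma = 1.4826 * float((diffs - diffs.median()).abs().median()) / np.sqrt(2.0)
        else:
            sigma = 0.0
        keep = (resid.abs() <= threshold_factor * max(sigma, 0.01)) & (depth > 0)
        keep_parts.append(grp[keep])
    out = pd.concat(keep_parts, ignore_index=True) if keep_parts else s.data.iloc[:0]
    removed = len(s) - len(out)
    if len(out) == 0:
        warnings.warn("despike removed every record")
    return s.with_data(out, "despike", window=window,
                       threshold_factor=threshold_factor, removed=removed)


def summarize(s: SoundingSet) -> SoundingSummary:
    """Depth distribution summary with adjusted Fisher-Pearson skewness."""
    d = s.data["depth"].to_numpy()
    if d.size < 3:
        raise ValueError("need at least 3 records for a skewness estimate")
    if np.ptp(d) == 0:
        return SoundingSummary(d.size, float(d[0]), float(d[0]), float(d[0]),
                               0.0, zero_variance=True)
    skew = float(stats.skew(d, bias=False))
    return SoundingSummary(d.size, float(d.min()), float(d.max()), float(d.mean()), skew)
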