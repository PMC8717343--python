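"""Random-forest presence/absence distribution models.

Stations carry a presence/absence record per species plus the multi-scale
terrain features extracted from a :class:`~bathysdm.terrain.TerrainStack`.
Each (species, bathymetry source) pair gets its own classifier; model skill
is the area under the ROC curve (AUC), reported both for a stratified
70/30 holdout and as stratified 5-fold cross-validation, and sources are
compared by a Welch t-test on the fold AUCs.  Conventional forest settings
are used throughout: 500 trees, sqrt(p) candidate features per split, no
class weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .grids import GridSurface
from .terrain import TerrainStack

N_TREES = 500
MIN_CLASS_RECOMMENDED = 35  # below this, models are flagged as unreliable


@dataclass
class StationTable:
    """Stations with coordinates, species presence columns and features."""

    data: pd.DataFrame
    feature_names: list[str]
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in ("x", "y"):
            if col not in self.data.columns:
                raise ValueError(f"station table missing column {col!r}")
        missing = [f for f in self.feature_names if f not in self.data.columns]
        if missing:
            raise ValueError(f"station table missing features: {missing}")
        for sp in self.species:
            vals = set(self.data[sp].unique())
            if not vals <= {0, 1}:
                raise ValueError(f"presence column {sp!r} must be 0/1")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    def presence(self, species: str) -> np.ndarray:
        if species not in self.data.columns:
            raise KeyError(f"unknown species {species!r}")
        return self.data[species].to_numpy(dtype=int)

    def prevalence(self, species: str) -> float:
        return float(self.presence(species).mean())


@dataclass
class SDMResult:
    """Fitted model with its evaluation artefacts for one species x source."""

    species: str
    source: str
    feature_names: list[str]
    model: RandomForestClassifier
    holdout_auc: float
    residuals: np.ndarray            # observed - predicted probability (test set)
    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_test: np.ndarray
    test_xy: np.ndarray
    fold_aucs: list[float] | None = None
    importance: dict[str, float] | None = None
    pdp: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def mean_auc(self) -> float | None:
        return float(np.mean(self.fold_aucs)) if self.fold_aucs else None


def extract_features(stack: TerrainStack, stations) -> StationTable:
    """Join nearest-cell stack values onto stations.

    ``stations`` is an (n, 2) array of (x, y) or a DataFrame with at least
    x/y columns (extra columns, e.g. presence records, are carried through).
    Stations falling on nodata in any layer, or off-grid, are dropped with a
    warning stating the count.  Feature order is deterministic: depth first,
    then variable-major, resolution-minor.
    """
    if isinstance(stations, pd.DataFrame):
        df = stations.reset_index(drop=True).copy()
    else:
        arr = np.asarray(stations, dtype=float)
        df = pd.DataFrame({"x": arr[:, 0], "y": arr[:, 1]})
    names = stack.feature_names
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    for name in names:
        df[name] = stack.layers[name].sample_nearest(x, y)
    ok = ~df[names].isna().any(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"{dropped} stations dropped (off-grid or on nodata cells)")
    species = [c for c in df.columns
               if c not in names and c not in ("x", "y")
               and set(pd.unique(df[c])) <= {0, 1}]
    return StationTable(df[ok].reset_index(drop=True), names, species)


def _check_classes(y: np.ndarray, species: str) -> None:
    pres, abs_ = int(y.sum()), int((1 - y).sum())
    if pres == 0 or abs_ == 0:
        raise ValueError(f"{species}: single-class records, cannot model")
    if min(pres, abs_) < MIN_CLASS_RECOMMENDED:
        warnings.warn(f"{species}: only {min(pres, abs_)} records in the rarer "
                      f"class (< {MIN_CLASS_RECOMMENDED}); model may be unreliable")


def _forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=N_TREES, max_features="sqrt",
                                  random_state=seed, n_jobs=1)


def fit_rf(table: StationTable, species: str, split_fraction: float = 0.7,
           seed: int = 0, source: str = "reference") -> SDMResult:
    """Train on a stratified 70/30 split; evaluate AUC and residuals on holdout.

    Residuals are observed - predicted probability on the test portion, so
    positive values are underpredictions.
    """
    y = table.presence(species)
    _check_classes(y, species)
    X = table.features
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(idx, train_size=split_fraction,
                                           stratify=y, random_state=seed)
    model = _forest(seed)
    model.fit(X.iloc[train_idx], y[train_idx])
    prob = model.predict_proba(X.iloc[test_idx])[:, 1]
    auc = float(roc_auc_score(y[test_idx], prob))
    residuals = y[test_idx] - prob
    return SDMResult(species, source, list(table.feature_names), model, auc,
                     residuals, X.iloc[train_idx], X.iloc[test_idx], y[test_idx],
                     table.data.iloc[test_idx][["x", "y"]].to_numpy())


def cv_auc(table: StationTable, species: str, folds: int = 5, seed: int = 0
           ) -> list[float]:
    """Stratified k-fold cross-validated AUC, one value per held-out fold."""
    y = table.presence(species)
    _check_classes(y, species)
    if min(int(y.sum()), int((1 - y).sum())) < folds:
        raise ValueError(f"{species}: rarer class too small for {folds} stratified folds")
    X = table.features
    aucs = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        model = _forest(seed)
        model.fit(X.iloc[train_idx], y[train_idx])
        prob = model.predict_proba(X.iloc[test_idx])[:, 1]
        aucs.append(float(roc_auc_score(y[test_idx], prob)))
    return aucs


def compare_auc(aucs_a: list[float], aucs_b: list[float]) -> tuple[float, float]:
    """Welch two-sample t-test on fold AUCs (two-sided); returns (t, p)."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length fold AUC lists of length >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def importance(result: SDMResult, n_repeats: int = 10, seed: int = 0
               ) -> list[tuple[str, float]]:
    """Permutation importance (mean held-out AUC drop) per variable, descending.

    Model-agnostic and less biased than impurity importance when features
    are correlated across scales, which multi-resolution terrain stacks
    always are.
    """
    perm = permutation_importance(result.model, result.X_test, result.y_test,
                                  scoring="roc_auc", n_repeats=n_repeats,
                                  random_state=seed)
    ranked = sorted(zip(result.feature_names, perm.importances_mean),
                    key=lambda kv: kv[1], reverse=True)
    result.importance = {k: float(v) for k, v in ranked}
    return [(k, float(v)) for k, v in ranked]


def partial_dependence(result: SDMResult, variable: str, grid_points: int = 20
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Partial dependence of predicted presence probability on one variable.

    The variable is clamped to each value of a quantile grid (2.5%-97.5% of
    the training data) while all other features keep their observed values;
    the mean predicted probability is returned per grid value.
    """
    if variable not in result.feature_names:
        raise KeyError(f"unknown variable {variable!r}")
    col = result.X_train[variable].to_numpy()
    grid = np.quantile(col, np.linspace(0.025, 0.975, grid_points))
    response = np.empty(grid_points)
    X = result.X_train.copy()
    for i, val in enumerate(grid):
        X[variable] = val
        response[i] = float(result.model.predict_proba(X)[:, 1].mean())
    result.pdp[variable] = (grid, response)
    return grid, response


def predict_surface(result: SDMResult, stack: TerrainStack) -> GridSurface:
    """Predicted probability of presence on the stack's native depth grid.

    Every model feature is sampled (nearest cell) onto the native grid;
    cells where any feature is nodata are nodata in the output.
    """
    missing = [f for f in result.feature_names if f not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing model features: {missing}")
    template = stack.layers[f"depth_{stack.native_cell:g}"]
    gx, gy = template.centre_mesh()
    cols = {f: stack.layers[f].sample_nearest(gx.ravel(), gy.ravel())
            for f in result.feature_names}
    X = pd.DataFrame(cols)
    ok = ~X.isna().any(axis=1).to_numpy()
    prob = np.full(len(X), np.nan)
    if ok.any():
        prob[ok] = result.model.predict_proba(X[ok])[:, 1]
    return template.copy_with(prob.reshape(template.values.shape))
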