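"""Ensemble habitat-suitability modeling and ecological vulnerability.

Presence records are spatially thinned, background points drawn from the
study grid, and five member classifiers (distinct generic families) are
each evaluated over replicated 70/30 calibration/validation splits.
Members enter the ensemble only if they pass the discrimination gates
(TSS > 0.8 and AUC > 0.9 by default); the ensemble suitability is the
TSS-weighted mean of the accepted members' probabilities.  Ecological
vulnerability is V_E = S_future - S_present per grid cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .grids import ClimateGrid, ClimateLayerSet
from .offset import EARTH_RADIUS_KM, haversine_km

__all__ = [
    "auc",
    "tss",
    "default_members",
    "make_presence_background",
    "EnsembleSDM",
    "suitability_map",
    "ecological_vulnerability",
    "cell_areas_km2",
    "habitat_area_change",
]


def auc(labels, scores) -> float:
    """Rank-based concordance (area under the ROC curve)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to compute AUC")
    return float(roc_auc_score(labels, scores))


def tss(labels, scores) -> float:
    """True skill statistic: max over thresholds of sensitivity + specificity - 1."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to compute TSS")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.max(tpr - fpr))


def default_members(random_state: int = 0) -> dict[str, BaseEstimator]:
    """Five generic model families standing in for RF/BRT/SVM/GAM/MaxEnt-style members."""
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=200, random_state=random_state
        ),
        "boosted_trees": GradientBoostingClassifier(random_state=random_state),
        "svm_rbf": make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(random_state=random_state),
                                   ensemble=False),
        ),
        "spline_additive": make_pipeline(
            StandardScaler(), SplineTransformer(n_knots=5, degree=3),
            LogisticRegression(max_iter=2000),
        ),
        "logistic": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000)
        ),
    }


def make_presence_background(
    occurrences: pd.DataFrame,
    layers: ClimateLayerSet,
    n_background: int = 10_000,
    thin_arcmin: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Thin presences and draw background cells; extract env at all points.

    Thinning is greedy in input order with a great-circle criterion of
    ``thin_arcmin`` arc-minutes (1 arc-min = 1/60 degree of arc).
    Background points are uniform over data cells that hold no retained
    presence, placed at cell centers.  Returns records with lon, lat,
    label ('presence'/'background') and env_<var> columns.
    """
    rng = np.random.default_rng(seed)
    grid = layers.geometry_grid()
    lon = occurrences["lon"].to_numpy(dtype=float)
    lat = occurrences["lat"].to_numpy(dtype=float)
    inside = grid.contains(lon, lat)
    if not inside.all():
        raise ValueError("occurrence records outside the grid extent")
    thin_km = thin_arcmin / 60.0 * (2 * np.pi * EARTH_RADIUS_KM / 360.0)
    keep: list[int] = []
    for i in range(lon.size):
        if all(
            haversine_km(lon[i], lat[i], lon[j], lat[j]) >= thin_km for j in keep
        ):
            keep.append(i)
    if not keep:
        raise ValueError("no presence records left after thinning")
    plon, plat = lon[keep], lat[keep]

    lon_g, lat_g = grid.cell_centers()
    data_mask = grid.mask()
    for g in layers.layers.values():
        data_mask &= g.mask()
    # cells occupied by a retained presence are excluded from the background
    ci = np.clip(((grid.yll + grid.nrows * grid.cellsize) - plat) // grid.cellsize, 0, grid.nrows - 1).astype(int)
    cj = np.clip((plon - grid.xll) // grid.cellsize, 0, grid.ncols - 1).astype(int)
    occupied = np.zeros_like(data_mask)
    occupied[ci, cj] = True
    candidates = np.flatnonzero((data_mask & ~occupied).ravel())
    if candidates.size == 0:
        raise ValueError("no background cells available")
    chosen = rng.choice(candidates, size=n_background,
                        replace=candidates.size < n_background)
    blon = lon_g.ravel()[chosen]
    blat = lat_g.ravel()[chosen]

    all_lon = np.concatenate([plon, blon])
    all_lat = np.concatenate([plat, blat])
    env = layers.extract(all_lon, all_lat)
    rec = pd.DataFrame({"lon": all_lon, "lat": all_lat})
    rec["label"] = ["presence"] * plon.size + ["background"] * blon.size
    for j, var in enumerate(layers.variables):
        rec[f"env_{var}"] = env[:, j]
    return rec


class EnsembleSDM(BaseEstimator):
    """Gated, weighted ensemble of habitat-suitability classifiers.

    fit(X, y) with y binary (1 = presence).  Each member is evaluated on
    ``n_replicates`` random ``calibration_frac`` splits; members whose
    mean validation TSS and AUC pass the gates are refitted on all data
    and weighted by mean TSS (normalized; ``weighting='equal'`` for flat
    weights).  ``threshold_`` is the ensemble's TSS-maximizing cutoff.
    """

    def __init__(self, members: dict[str, BaseEstimator] | None = None,
                 n_replicates: int = 10, calibration_frac: float = 0.7,
                 tss_gate: float = 0.8, auc_gate: float = 0.9,
                 weighting: str = "tss", random_state: int = 0):
        self.members = members
        self.n_replicates = n_replicates
        self.calibration_frac = calibration_frac
        self.tss_gate = tss_gate
        self.auc_gate = auc_gate
        self.weighting = weighting
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        members = self.members or default_members(self.random_state)
        rows = []
        for name, proto in members.items():
            aucs, tsss = [], []
            for rep in range(self.n_replicates):
                Xtr, Xva, ytr, yva = train_test_split(
                    X, y, train_size=self.calibration_frac, stratify=y,
                    random_state=self.random_state * 1000 + rep,
                )
                est = clone(proto).fit(Xtr, ytr)
                s = self._scores(est, Xva)
                aucs.append(auc(yva, s))
                tsss.append(tss(yva, s))
            rows.append({"member": name, "auc": float(np.mean(aucs)),
                         "tss": float(np.mean(tsss))})
        self.member_metrics_ = pd.DataFrame(rows).set_index("member")
        passed = self.member_metrics_[
            (self.member_metrics_["tss"] > self.tss_gate)
            & (self.member_metrics_["auc"] > self.auc_gate)
        ]
        if passed.empty:
            raise ValueError(
                "all members failed the TSS/AUC gates:\n"
                f"{self.member_metrics_.round(3)}"
            )
        self.accepted_ = list(passed.index)
        if self.weighting == "equal":
            w = np.ones(len(passed))
        else:
            w = passed["tss"].to_numpy()
        self.weights_ = dict(zip(passed.index, w / w.sum()))
        self.fitted_members_ = {
            name: clone(members[name]).fit(X, y) for name in self.accepted_
        }
        s = self.predict_suitability(X)
        fpr, tpr, thr = roc_curve(y, s)
        self.threshold_ = float(thr[np.argmax(tpr - fpr)])
        return self

    @staticmethod
    def _scores(est, X):
        return est.predict_proba(X)[:, 1]

    def predict_suitability(self, X) -> np.ndarray:
        """Weighted-mean member probability of presence, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        for name, est in self.fitted_members_.items():
            out += self.weights_[name] * self._scores(est, X)
        return out


def suitability_map(model: EnsembleSDM, layers: ClimateLayerSet,
                    variables: list[str]) -> np.ndarray:
    """Per-cell ensemble suitability grid in [0, 1]; nodata becomes NaN."""
    missing = [v for v in variables if v not in layers.layers]
    if missing:
        raise KeyError(f"missing climate layer(s): {missing}")
    stack = layers.stack(variables)
    nrows, ncols, p = stack.shape
    mask = np.ones((nrows, ncols), dtype=bool)
    for v in variables:
        mask &= layers[v].mask()
    flat = stack.reshape(-1, p)
    out = np.full(flat.shape[0], np.nan)
    ok = mask.ravel()
    if ok.any():
        out[ok] = model.predict_suitability(flat[ok])
    return out.reshape(nrows, ncols)


def ecological_vulnerability(s_future: np.ndarray, s_present: np.ndarray) -> np.ndarray:
    """V_E = S_future - S_present, per co-registered cell (in [-1, 1])."""
    s_future = np.asarray(s_future, dtype=float)
    s_present = np.asarray(s_present, dtype=float)
    if s_future.shape != s_present.shape:
        raise ValueError("suitability grids are not co-registered")
    return s_future - s_present


def cell_areas_km2(grid: ClimateGrid) -> np.ndarray:
    """Latitude-dependent spherical cell areas, km^2, per grid cell."""
    _, lat = grid.cell_centers()
    dlat = np.radians(grid.cellsize)
    dlon = np.radians(grid.cellsize)
    return (EARTH_RADIUS_KM**2) * dlon * dlat * np.cos(np.radians(lat))


def habitat_area_change(
    s_present: np.ndarray,
    s_future: np.ndarray,
    threshold: float,
    cell_areas: np.ndarray,
) -> float:
    """Percent change in area-weighted suitable habitat (S >= threshold)."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    sp = np.asarray(s_present, dtype=float)
    sf = np.asarray(s_future, dtype=float)
    w = np.asarray(cell_areas, dtype=float)
    a_p = np.nansum(np.where(sp >= threshold, w, 0.0))
    a_f = np.nansum(np.where(sf >= threshold, w, 0.0))
    if a_p == 0:
        return float("nan")
    return float((a_f - a_p) / a_p * 100.0)
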