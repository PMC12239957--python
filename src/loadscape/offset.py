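"""Genotype-climate turnover models and genomic-offset maps.

A turnover model maps each climate variable through a fitted monotone
non-decreasing transform into a compositional-importance space where the
expected allele-frequency turnover between two climates is the Euclidean
distance between their transformed vectors.  Two models are provided:

* :class:`GradientForestTurnover` — per-SNP regression forests of allele
  frequency on climate; split-importance is accumulated along each
  variable's axis (weighted by per-SNP fit quality) into a cumulative-
  importance step function.
* :class:`DissimilaritySplineTurnover` — generalized-dissimilarity-style
  regression of rescaled pairwise Fst on non-negative I-spline basis
  differences, giving smooth monotone transforms.

Offsets in the transformed space:

* local    — distance between a cell's present and future vectors;
* forward  — minimum distance from a cell's present vector to the future
  vector of any cell within a great-circle dispersal cap (the focal cell
  is always in the pool, so forward <= local);
* reverse  — minimum distance from a future cell's vector to any current
  cell's present vector (no dispersal cap).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

from .grids import ClimateLayerSet

__all__ = [
    "GradientForestTurnover",
    "DissimilaritySplineTurnover",
    "haversine_km",
    "transform_climate",
    "local_offset",
    "forward_offset",
    "reverse_offset",
    "rgb_composite",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------------------
# turnover models


class GradientForestTurnover(BaseEstimator):
    """Gradient-forest style cumulative-importance turnover model.

    fit(X, F) with X the (n_sites, n_vars) climate matrix at sampling
    sites and F the (n_sites, n_snps) allele-frequency matrix of the
    candidate SNPs.  Per SNP a random forest regresses frequency on
    climate; each split's impurity decrease is credited to its variable
    at its threshold, weighted by the SNP's out-of-bag fit quality
    (R^2, clipped at 0; SNPs with non-positive fit are dropped).

    After fit, ``cumulative_importance_`` maps each variable name to
    (thresholds, cumulative values) defining a monotone non-decreasing
    step transform, and ``variable_importance_`` holds each transform's
    total height.
    """

    def __init__(self, n_estimators: int = 100, min_samples_leaf: int = 2,
                 max_features: float = 1.0, random_state: int | None = 0):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, F, variables: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        F = np.asarray(F, dtype=float)
        n_sites, p = X.shape
        if n_sites < 5:
            raise ValueError("need at least 5 sites/populations")
        self.variables_ = list(variables) if variables is not None else [
            f"x{j}" for j in range(p)
        ]
        const = X.std(axis=0) == 0
        if const.any():
            warnings.warn(
                f"constant variable(s) {[self.variables_[j] for j in np.flatnonzero(const)]}: "
                "zero transform", stacklevel=2,
            )
        splits: dict[int, list[tuple[float, float]]] = {j: [] for j in range(p)}
        self.snp_r2_ = np.full(F.shape[1], np.nan)
        rng = np.random.default_rng(self.random_state)
        kept = 0
        for m in range(F.shape[1]):
            y = F[:, m]
            if y.std() == 0:
                continue
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators,
                min_samples_leaf=self.min_samples_leaf,
                max_features=self.max_features,
                bootstrap=True,
                oob_score=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny-n OOB warnings
                rf.fit(X, y)
                r2 = rf.oob_score_ if np.isfinite(rf.oob_score_) else -np.inf
            self.snp_r2_[m] = r2
            if r2 <= 0:
                continue  # SNP carries no turnover signal
            kept += 1
            raw: dict[int, list[tuple[float, float]]] = {j: [] for j in range(p)}
            total = 0.0
            for tree in rf.estimators_:
                t = tree.tree_
                w = t.weighted_n_node_samples / t.weighted_n_node_samples[0]
                for node in range(t.node_count):
                    left, right = t.children_left[node], t.children_right[node]
                    if left == -1:
                        continue
                    dec = (
                        w[node] * t.impurity[node]
                        - w[left] * t.impurity[left]
                        - w[right] * t.impurity[right]
                    )
                    if dec <= 0:
                        continue
                    raw[t.feature[node]].append((t.threshold[node], dec))
                    total += dec
            if total <= 0:
                continue
            scale = r2 / total  # per-SNP importance sums to its R^2
            for j in range(p):
                splits[j].extend((thr, dec * scale) for thr, dec in raw[j])
        if kept == 0:
            raise ValueError("no SNP had positive out-of-bag fit; cannot build transforms")
        self.n_snps_used_ = kept
        self.cumulative_importance_ = {}
        self.variable_importance_ = {}
        for j, var in enumerate(self.variables_):
            if splits[j]:
                arr = np.array(sorted(splits[j]))
                thr = arr[:, 0]
                cum = np.cumsum(arr[:, 1]) / kept
            else:
                thr = np.array([0.0])
                cum = np.array([0.0])
            self.cumulative_importance_[var] = (thr, cum)
            self.variable_importance_[var] = float(cum[-1])
        self._train_min = X.min(axis=0)
        self._train_max = X.max(axis=0)
        return self

    def transform_variables(self, V: np.ndarray) -> np.ndarray:
        """Map (N, n_vars) raw climate values through the step transforms.

        Values beyond the training range clamp to the boundary transform
        value (a step function is constant outside its split range).
        """
        V = np.asarray(V, dtype=float)
        out = np.zeros_like(V)
        for j, var in enumerate(self.variables_):
            thr, cum = self.cumulative_importance_[var]
            idx = np.searchsorted(thr, V[:, j], side="right")
            vals = np.concatenate([[0.0], cum])
            out[:, j] = vals[idx]
        return out


def _ispline_basis(x: np.ndarray, xmin: float, xmax: float, n_basis: int = 3,
                   degree: int = 2) -> np.ndarray:
    """Monotone I-spline basis on [xmin, xmax], each column in [0, 1].

    I-splines are integrated M-splines; computed by cumulative trapezoid
    integration of the normalized B-spline basis on a fine grid, then
    interpolated at the query points (clamped to the training range).
    """
    if xmax <= xmin:
        return np.zeros((np.asarray(x).size, n_basis))
    n_interior = max(n_basis - degree + 1, 0)
    interior = np.linspace(xmin, xmax, n_interior + 2)[1:-1] if n_interior else []
    t = np.concatenate([[xmin] * (degree + 1), interior, [xmax] * (degree + 1)])
    grid = np.linspace(xmin, xmax, 1025)
    n_b = len(t) - degree - 1
    design = np.column_stack([
        BSpline.basis_element(t[k: k + degree + 2], extrapolate=False)(grid)
        for k in range(n_b)
    ])
    design = np.nan_to_num(design)
    # integrate each M-spline-shaped basis to a monotone curve in [0, 1]
    dx = grid[1] - grid[0]
    integ = np.cumsum((design[:-1] + design[1:]) / 2, axis=0) * dx
    integ = np.vstack([np.zeros(n_b), integ])
    integ /= np.maximum(integ[-1], 1e-300)
    xq = np.clip(np.asarray(x, dtype=float), xmin, xmax)
    out = np.column_stack([np.interp(xq, grid, integ[:, k]) for k in range(n_b)])
    return out[:, :n_basis] if n_b >= n_basis else out


class DissimilaritySplineTurnover(BaseEstimator):
    """Monotone I-spline turnover fitted to pairwise Fst dissimilarities.

    fit(fst, X) with ``fst`` a symmetric (P, P) matrix (diagonal 0) and X
    the (P, n_vars) climate matrix at the populations.  Fst is rescaled
    to [0, 1]; the rescaled dissimilarity of each pair is regressed on
    the per-variable absolute I-spline basis differences (plus optional
    great-circle distance) with non-negative coefficients, so every
    fitted per-variable transform is monotone non-decreasing.
    """

    def __init__(self, n_basis: int = 3, degree: int = 2,
                 use_geographic_distance: bool = False):
        self.n_basis = n_basis
        self.degree = degree
        self.use_geographic_distance = use_geographic_distance

    def fit(self, fst, X, variables: list[str] | None = None,
            coords: np.ndarray | None = None):
        fst = np.asarray(fst, dtype=float)
        X = np.asarray(X, dtype=float)
        P = fst.shape[0]
        if fst.shape != (P, P) or X.shape[0] != P:
            raise ValueError("fst must be (P, P) and X (P, n_vars)")
        if P < 4:
            raise ValueError("need at least 4 populations")
        if not np.allclose(fst, fst.T, atol=1e-8) or not np.allclose(np.diag(fst), 0):
            raise ValueError("fst must be symmetric with zero diagonal")
        p = X.shape[1]
        self.variables_ = list(variables) if variables is not None else [
            f"x{j}" for j in range(p)
        ]
        iu = np.triu_indices(P, k=1)
        y = fst[iu]
        lo, hi = y.min(), y.max()
        self.fst_range_ = (float(lo), float(hi))
        y = (y - lo) / (hi - lo) if hi > lo else np.zeros_like(y)

        self._xmin = X.min(axis=0)
        self._xmax = X.max(axis=0)
        cols = []
        for j in range(p):
            B = _ispline_basis(X[:, j], self._xmin[j], self._xmax[j],
                               self.n_basis, self.degree)
            cols.append(np.abs(B[iu[0]] - B[iu[1]]))
        D = np.hstack(cols)
        if self.use_geographic_distance:
            if coords is None:
                raise ValueError("coords required with use_geographic_distance")
            gd = haversine_km(coords[iu[0], 0], coords[iu[0], 1],
                              coords[iu[1], 0], coords[iu[1], 1])
            D = np.hstack([D, (gd / max(gd.max(), 1e-12))[:, None]])
        # free intercept via +/- columns; slope coefficients stay non-negative
        A = np.hstack([D, np.ones((D.shape[0], 1)), -np.ones((D.shape[0], 1))])
        coef, _ = nnls(A, y)
        self.intercept_ = float(coef[-2] - coef[-1])
        slopes = coef[: D.shape[1]]
        self.coefs_ = {
            var: slopes[j * self.n_basis: (j + 1) * self.n_basis]
            for j, var in enumerate(self.variables_)
        }
        if self.use_geographic_distance:
            self.geo_coef_ = float(slopes[-1])
        self.variable_importance_ = {
            var: float(a.sum()) for var, a in self.coefs_.items()
        }
        return self

    def transform_variables(self, V: np.ndarray) -> np.ndarray:
        """Map (N, n_vars) climate values through the fitted I-spline transforms."""
        V = np.asarray(V, dtype=float)
        out = np.zeros_like(V)
        for j, var in enumerate(self.variables_):
            B = _ispline_basis(V[:, j], self._xmin[j], self._xmax[j],
                               self.n_basis, self.degree)
            out[:, j] = B @ self.coefs_[var]
        return out


# ---------------------------------------------------------------------------
# offset operators


def transform_climate(model, layers: ClimateLayerSet) -> np.ndarray:
    """Transformed climate per cell: (nrows, ncols, n_vars) array.

    Cells without data in any layer become NaN in every band.
    """
    missing = [v for v in model.variables_ if v not in layers.layers]
    if missing:
        raise KeyError(f"missing climate layer(s): {missing}")
    stack = layers.stack(model.variables_)
    nrows, ncols, p = stack.shape
    mask = np.ones((nrows, ncols), dtype=bool)
    for v in model.variables_:
        mask &= layers[v].mask()
    flat = stack.reshape(-1, p)
    out = np.full_like(flat, np.nan, dtype=float)
    ok = mask.ravel()
    out[ok] = model.transform_variables(flat[ok])
    return out.reshape(nrows, ncols, p)


def _check_geometry(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")


def local_offset(t_present: np.ndarray, t_future: np.ndarray) -> np.ndarray:
    """Per-cell Euclidean distance between transformed present and future."""
    _check_geometry(t_present, t_future)
    return np.sqrt(np.sum((t_future - t_present) ** 2, axis=-1))


def _pairwise_setup(t_present, t_future):
    nrows, ncols, p = t_present.shape
    A = t_present.reshape(-1, p)
    B = t_future.reshape(-1, p)
    okA = np.isfinite(A).all(axis=1)
    okB = np.isfinite(B).all(axis=1)
    return A, B, okA, okB, (nrows, ncols)


def forward_offset(
    t_present: np.ndarray,
    t_future: np.ndarray,
    lon: np.ndarray,
    lat: np.ndarray,
    max_km: float = np.inf,
) -> np.ndarray:
    """Minimum offset to any future cell within the dispersal cap.

    ``lon``/``lat`` are cell-center coordinate grids.  The focal cell is
    always inside its own pool, so forward <= local cell-wise.  A cap
    smaller than the cell spacing degenerates to the local offset.
    """
    _check_geometry(t_present, t_future)
    if not (max_km > 0):
        raise ValueError("max_km must be > 0 (use np.inf for no cap)")
    A, B, okA, okB, shape = _pairwise_setup(t_present, t_future)
    lonf, latf = np.asarray(lon).ravel(), np.asarray(lat).ravel()
    out = np.full(A.shape[0], np.nan)
    ia = np.flatnonzero(okA)
    ib = np.flatnonzero(okB)
    if ia.size and ib.size:
        for i in ia:
            if np.isinf(max_km):
                pool = ib
            else:
                gd = haversine_km(lonf[i], latf[i], lonf[ib], latf[ib])
                pool = ib[(gd <= max_km) | (ib == i)]
            d = np.sqrt(np.sum((B[pool] - A[i]) ** 2, axis=1))
            out[i] = d.min()
    return out.reshape(shape)


def reverse_offset(t_present: np.ndarray, t_future: np.ndarray) -> np.ndarray:
    """Per-future-cell minimum offset from any current cell (no cap)."""
    _check_geometry(t_present, t_future)
    A, B, okA, okB, shape = _pairwise_setup(t_present, t_future)
    out = np.full(B.shape[0], np.nan)
    ia = np.flatnonzero(okA)
    ib = np.flatnonzero(okB)
    if ia.size and ib.size:
        for j in ib:
            d = np.sqrt(np.sum((A[ia] - B[j]) ** 2, axis=1))
            out[j] = d.min()
    return out.reshape(shape)


def rgb_composite(local: np.ndarray, forward: np.ndarray, reverse: np.ndarray) -> np.ndarray:
    """Min-max scaled RGB image: local -> R, forward -> G, reverse -> B.

    Nodata (NaN) propagates; a constant band scales to 0 with a warning.
    """
    bands = []
    for name, band in (("local", local), ("forward", forward), ("reverse", reverse)):
        b = np.asarray(band, dtype=float)
        ok = np.isfinite(b)
        if ok.any():
            lo, hi = b[ok].min(), b[ok].max()
            if hi > lo:
                scaled = (b - lo) / (hi - lo)
            else:
                warnings.warn(f"constant {name} band scaled to 0", stacklevel=2)
                scaled = np.where(ok, 0.0, np.nan)
        else:
            scaled = b
        bands.append(scaled)
    return np.stack(bands, axis=-1)
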