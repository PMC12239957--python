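"""Genotype-environment association: the two-method candidate screen.

Climate-associated SNPs are called by the intersection of two methods:

* :class:`RdaScan` — constrained ordination (redundancy analysis) of
  centered dosages on the pruned climate variables; axes kept at
  permutation P < 0.05; a SNP is an outlier if its loading on any
  significant axis lies more than 2 SDs from the mean loading.
* :class:`LatentFactorScan` — per-SNP association of dosage with the
  climate variables conditioned on K latent factors (top principal axes
  of the dosage matrix, K = 2 by default), Benjamini-Hochberg FDR < 0.05.

Collinear climate variables are first removed with :class:`VifPruner`
(iterative removal of the largest variance-inflation factor until all
VIF <= 10).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VifPruner",
    "RdaScan",
    "LatentFactorScan",
    "intersect_gea",
    "genomic_inflation",
    "impute_dosage",
]


def impute_dosage(dosage: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages (<0) per SNP; returns float array."""
    g = np.asarray(dosage, dtype=float)
    g = np.where(g < 0, np.nan, g)
    called = np.isfinite(g).sum(axis=0)
    totals = np.nansum(g, axis=0)
    means = np.where(called > 0, totals / np.maximum(called, 1), 0.0)
    idx = np.where(np.isnan(g))
    g[idx] = means[idx[1]]
    return g


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column of a centered design."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"column {j} is constant; singular design")
        r2 = 1 - np.sum(resid**2) / ss_tot
        out[j] = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
    return out


class VifPruner(BaseEstimator, TransformerMixin):
    """Iteratively drop the highest-VIF variable until all VIFs <= threshold.

    Ties in the maximum VIF are broken by variable name order, making the
    result invariant to input column ordering.
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(arr.shape[1])]
        if arr.shape[1] < 1:
            raise ValueError("need at least one variable")
        if arr.shape[0] < arr.shape[1] + 1:
            raise ValueError("need at least n_variables + 1 observations")
        keep = list(range(arr.shape[1]))
        dropped: list[str] = []
        while len(keep) > 1:
            vifs = _vif(arr[:, keep])
            mx = vifs.max()
            if mx <= self.threshold:
                break
            # ties broken by name order
            tied = [keep[i] for i in np.flatnonzero(vifs == mx)]
            worst = min(tied, key=lambda j: names[j])
            dropped.append(names[worst])
            keep.remove(worst)
        self.retained_ = [names[j] for j in keep]
        self.dropped_ = dropped
        self.vifs_ = dict(zip(self.retained_, _vif(arr[:, keep])))
        self._keep_idx = keep
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.retained_]
        return np.asarray(X, dtype=float)[:, self._keep_idx]


class RdaScan(BaseEstimator):
    """Redundancy-analysis loading-outlier scan, conditioned on structure.

    fit(X, Y) with X the (n_samples, n_env) climate matrix and Y the
    (n_samples, n_snps) dosage matrix.  Both the dosages and the climate
    matrix are first residualized on ``k_condition`` structure axes (the
    top principal components of the standardized dosage matrix), the
    partial-ordination practice for structure-confounded landscapes;
    ``k_condition=0`` gives a plain RDA.  Axis significance is assessed
    by permuting sample rows ``n_permutations`` times and comparing each
    constrained eigenvalue with its permutation distribution; a SNP is
    an outlier when its loading on any significant axis lies more than
    ``sd_mult`` SDs from the mean loading.

    Attributes (after fit): ``eigenvalues_``, ``axis_pvalues_``,
    ``significant_axes_``, ``loadings_`` (n_snps, n_axes) and
    ``outlier_mask_``.
    """

    def __init__(self, n_permutations: int = 999, alpha: float = 0.05,
                 sd_mult: float = 2.0, k_condition: int = 2,
                 random_state: int | None = 0):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.sd_mult = sd_mult
        self.k_condition = k_condition
        self.random_state = random_state

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p > n - 1:
            raise ValueError("more constraints than samples - 1")
        if np.any(X.std(axis=0) == 0):
            raise ValueError("constant environmental column")
        G = impute_dosage(Y)
        Yc = G - G.mean(axis=0)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        groups = [np.arange(n)]
        if self.k_condition > 0:
            sd = Yc.std(axis=0)
            Gs = Yc / np.where(sd > 0, sd, 1.0)
            U, sv, _ = np.linalg.svd(Gs, full_matrices=False)
            C = np.column_stack([np.ones(n), U[:, : self.k_condition]])
            Hc = C @ np.linalg.pinv(C)
            Yc = Yc - Hc @ Yc
            Xs = Xs - Hc @ Xs
            # permutations restricted to strata from the structure axes:
            # individuals are exchangeable within, not across, genetic groups
            n_clusters = max(1, min(self.k_condition, n // 2))
            scores = U[:, : self.k_condition] * sv[: self.k_condition]
            labels = KMeans(n_clusters=n_clusters, n_init=5,
                            random_state=0).fit_predict(scores)
            groups = [np.flatnonzero(labels == c) for c in range(n_clusters)]
        Q, _ = np.linalg.qr(Xs)
        M = Q.T @ Yc  # fitted values in the orthonormal env basis
        _, sval, Vt = np.linalg.svd(M, full_matrices=False)
        n_axes = int(np.sum(sval > 1e-10 * max(sval.max(), 1)))
        sval = sval[:n_axes]
        Vt = Vt[:n_axes]
        self.eigenvalues_ = sval**2 / (n - 1)

        rng = np.random.default_rng(self.random_state)
        exceed = np.zeros(n_axes)
        for _ in range(self.n_permutations):
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(g.size)]
            sp = np.linalg.svd(Q.T @ Yc[perm], compute_uv=False)[:n_axes]
            exceed += sp**2 / (n - 1) >= self.eigenvalues_ - 1e-12
        self.axis_pvalues_ = (1.0 + exceed) / (self.n_permutations + 1.0)
        # sequential gatekeeping: a later axis only counts if every earlier
        # axis is significant (marginal tests of later ordered eigenvalues
        # are anticonservative on their own)
        sig = self.axis_pvalues_ < self.alpha
        stop = int(np.argmin(sig)) if not sig.all() else len(sig)
        self.significant_axes_ = np.arange(stop)

        # SNP loadings ("species scores"): right singular vectors x singular values
        self.loadings_ = (Vt.T * sval)
        out = np.zeros(Y.shape[1], dtype=bool)
        for k in self.significant_axes_:
            lk = self.loadings_[:, k]
            out |= np.abs(lk - lk.mean()) > self.sd_mult * lk.std()
        self.outlier_mask_ = out
        return self

    def loading_outliers(self, axis: int = 0) -> np.ndarray:
        """2-SD outlier mask on one axis regardless of significance gating."""
        lk = self.loadings_[:, axis]
        return np.abs(lk - lk.mean()) > self.sd_mult * lk.std()


class LatentFactorScan(BaseEstimator):
    """Latent-factor association scan with BH-FDR candidate calling.

    Latent factors are the top ``k`` axes of the column-standardized
    (EIGENSTRAT-scaled) dosage matrix — they absorb genome-wide
    population structure, while a sparse block of high-variance adaptive
    loci cannot hijack an axis and soak up the tested signal.  Each
    SNP's dosage is regressed on the climate variables plus the factors
    and the climate block is tested jointly (F-type statistic).

    Post-bottleneck dosage matrices are heavily discrete (many sites
    monomorphic within one population) and individual noise levels
    differ between populations, so parametric F p-values are not
    calibrated at n ~ tens of individuals; by default p-values come from
    a Freedman-Lane residual-permutation null (restricted to strata from
    clustering the factor scores) pooled across SNPs.
    ``calibration='parametric'`` restores plain F-test p-values.

    ``mode='univariate'`` tests each variable separately and keeps the
    Bonferroni-adjusted minimum p per SNP.

    Attributes: ``pvalues_``, ``qvalues_``, ``candidate_mask_``,
    ``factors_``, ``fstats_``.
    """

    def __init__(self, k: int = 2, fdr: float = 0.05, mode: str = "joint",
                 calibration: str = "permutation",
                 n_null_permutations: int = 250,
                 random_state: int | None = 0):
        self.k = k
        self.fdr = fdr
        self.mode = mode
        self.calibration = calibration
        self.n_null_permutations = n_null_permutations
        self.random_state = random_state

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        n, q = X.shape
        if self.k >= n:
            raise ValueError("k must be smaller than the number of samples")
        if np.any(X.std(axis=0) == 0):
            raise ValueError("constant environmental column")
        if self.calibration not in ("permutation", "parametric"):
            raise ValueError("calibration must be 'permutation' or 'parametric'")
        G = impute_dosage(Y)
        Gc = G - G.mean(axis=0)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        factors = self._estimate_factors(Gc)
        self.factors_ = factors

        if self.mode == "joint":
            self.pvalues_, self.fstats_ = self._scan(Gc, Xs, factors)
        elif self.mode == "univariate":
            cols = [self._scan(Gc, Xs[:, [j]], factors) for j in range(q)]
            ps = np.column_stack([c[0] for c in cols])
            self.fstats_ = np.column_stack([c[1] for c in cols]).max(axis=1)
            self.pvalues_ = np.minimum(ps.min(axis=1) * q, 1.0)
        else:
            raise ValueError("mode must be 'joint' or 'univariate'")
        self.qvalues_ = multipletests(self.pvalues_, method="fdr_bh")[1]
        self.candidate_mask_ = self.qvalues_ < self.fdr
        return self

    def _scan(self, Gc, Xs, factors):
        n = Gc.shape[0]
        q = Xs.shape[1]

        def projectors(fac):
            Z0 = np.column_stack([np.ones(n), fac])
            Z1 = np.column_stack([Z0, Xs])
            M0 = np.eye(n) - Z0 @ np.linalg.pinv(Z0)
            M1 = np.eye(n) - Z1 @ np.linalg.pinv(Z1)
            return M0, M1, n - Z1.shape[1]

        def fstat(Y, M0, M1, df2):
            rss0 = np.sum((M0 @ Y) ** 2, axis=0)
            rss1 = np.sum((M1 @ Y) ** 2, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = ((rss0 - rss1) / q) / (rss1 / df2)
            return np.where(np.isfinite(f), np.maximum(f, 0.0), 0.0)

        M0, M1, df2 = projectors(factors)
        if df2 <= 0:
            raise ValueError("not enough samples for the regression")
        f_obs = fstat(Gc, M0, M1, df2)
        if self.calibration == "parametric":
            return stats.f.sf(f_obs, q, df2), f_obs
        # Freedman-Lane null: permute the null-model residuals within
        # strata given by clustering the factor scores (individuals are
        # exchangeable within, not across, genetic groups), re-run the
        # pipeline (factor estimation included) on each pseudo dataset,
        # and pool the null F statistics across SNPs
        rng = np.random.default_rng(self.random_state)
        if self.k > 0:
            n_clusters = max(1, min(self.k, n // 2))
            labels = KMeans(n_clusters=n_clusters, n_init=5,
                            random_state=0).fit_predict(factors)
            groups = [np.flatnonzero(labels == c) for c in range(n_clusters)]
        else:
            groups = [np.arange(n)]
        R0 = M0 @ Gc
        fitted = Gc - R0
        pool = np.empty((self.n_null_permutations, Gc.shape[1]))
        for b in range(self.n_null_permutations):
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(g.size)]
            Yb = fitted + R0[perm]
            M0b, M1b, _ = projectors(self._estimate_factors(Yb))
            pool[b] = fstat(Yb, M0b, M1b, df2)
        flat = np.sort(pool.ravel())
        exceed = flat.size - np.searchsorted(flat, f_obs, side="left")
        p = (1.0 + exceed) / (flat.size + 1.0)
        return p, f_obs

    def _estimate_factors(self, Gc: np.ndarray) -> np.ndarray:
        """Top-k axes of the column-standardized (EIGENSTRAT-scaled) matrix.

        Standardization keeps genome-wide structure dominant in the
        spectrum while a sparse block of high-variance adaptive loci
        cannot hijack an axis and soak up the tested signal.
        """
        if self.k == 0:
            return np.empty((Gc.shape[0], 0))
        sd = Gc.std(axis=0)
        Gs = Gc / np.where(sd > 0, sd, 1.0)
        U, sv, _ = np.linalg.svd(Gs, full_matrices=False)
        return U[:, : self.k] * sv[: self.k]


def intersect_gea(rda_mask: np.ndarray, lf_mask: np.ndarray) -> dict:
    """Two-method intersection; a candidate must be flagged by both."""
    rda_mask = np.asarray(rda_mask, bool)
    lf_mask = np.asarray(lf_mask, bool)
    both = rda_mask & lf_mask
    return {
        "candidate_mask": both,
        "n_rda": int(rda_mask.sum()),
        "n_latent_factor": int(lf_mask.sum()),
        "n_candidates": int(both.sum()),
    }


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median association chi2 over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = np.clip(p[np.isfinite(p)], 1e-300, 1.0)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
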