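"""Sliding-window selection scan: Fst, nucleotide diversity, outliers.

Window Fst is the Weir & Cockerham (1984) weighted estimator: variance
components a, b, c are computed per SNP and summed over the window,
Fst = sum(a) / sum(a+b+c) — the behavior of the standard VCF windowed
scan.  A Hudson-style estimator is available behind a flag.  Pairwise
nucleotide diversity per window divides the summed per-site heterozygosity
by the window length in bp (monomorphic positions count as invariant).

Windows are 0-based half-open internally and in BED outputs.  Scaffolds
shorter than one window length are skipped.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "wc_fst_components",
    "hudson_fst_components",
    "site_pi",
    "windowed_fst",
    "pi_ratio",
    "top_quantile_outliers",
    "intersect_candidates",
]


def _freqs_and_het(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site called diploid count, alt-allele freq, observed het freq."""
    called = dosage >= 0
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dosage, 0).sum(axis=0) / np.maximum(2 * n, 1)
        h = np.where(called, dosage == 1, False).sum(axis=0) / np.maximum(n, 1)
    return n, p, h


def wc_fst_components(gA: np.ndarray, gB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham per-SNP variance components for two populations.

    Returns (a, a+b+c); sites with fewer than 2 called diploids in either
    population get NaN components.
    """
    nA, pA, hA = _freqs_and_het(gA)
    nB, pB, hB = _freqs_and_het(gB)
    r = 2.0
    valid = (nA >= 2) & (nB >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    a = np.where(valid, a, np.nan)
    tot = np.where(valid, a + b + c, np.nan)
    return a, tot


def hudson_fst_components(gA: np.ndarray, gB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hudson estimator per-SNP numerator and denominator."""
    nA, pA, _ = _freqs_and_het(gA)
    nB, pB, _ = _freqs_and_het(gB)
    nA2, nB2 = 2 * nA, 2 * nB
    valid = (nA2 >= 2) & (nB2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (pA - pB) ** 2
            - pA * (1 - pA) / (nA2 - 1)
            - pB * (1 - pB) / (nB2 - 1)
        )
        den = pA * (1 - pB) + pB * (1 - pA)
    return np.where(valid, num, np.nan), np.where(valid, den, np.nan)


def site_pi(dosage: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity from called allele counts."""
    called = dosage >= 0
    n = 2 * called.sum(axis=0).astype(float)
    d = np.where(called, dosage, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, d * (n - d) / (n * (n - 1) / 2), np.nan)
    return pi


def windowed_fst(
    dosage: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    pop_a_mask: np.ndarray,
    pop_b_mask: np.ndarray,
    window: int = 50_000,
    step: int = 25_000,
    min_snps: int = 3,
    chrom_lengths: dict[str, int] | None = None,
    estimator: str = "wc",
) -> pd.DataFrame:
    """Sliding-window Fst and per-population diversity.

    ``pos`` is 1-based (VCF convention); windows are 0-based half-open.
    Returns one row per window with columns chrom, start, end, n_snps,
    fst, pi_popA, pi_popB, pi_ratio and a low_support flag for windows
    with fewer than ``min_snps`` SNPs.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    if estimator == "wc":
        comp = wc_fst_components
    elif estimator == "hudson":
        comp = hudson_fst_components
    else:
        raise ValueError("estimator must be 'wc' or 'hudson'")
    gA = dosage[np.asarray(pop_a_mask, bool)]
    gB = dosage[np.asarray(pop_b_mask, bool)]
    num, den = comp(gA, gB)
    pi_a = site_pi(gA)
    pi_b = site_pi(gB)

    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    rows = []
    for c in pd.unique(chrom):
        on_c = np.flatnonzero(chrom == c)
        length = (
            chrom_lengths[str(c)] if chrom_lengths and str(c) in chrom_lengths
            else int(pos[on_c].max())
        )
        if length < window:
            continue  # scaffold shorter than one window
        p0 = pos[on_c] - 1  # 0-based
        for start in range(0, length, step):
            end = min(start + window, length)
            in_w = on_c[(p0 >= start) & (p0 < end)]
            n_snps = in_w.size
            dsum = np.nansum(den[in_w]) if n_snps else np.nan
            fst = (
                float(np.nansum(num[in_w]) / dsum)
                if n_snps and np.isfinite(dsum) and dsum != 0
                else np.nan
            )
            span = end - start
            pa = float(np.nansum(pi_a[in_w])) / span if n_snps else 0.0
            pb = float(np.nansum(pi_b[in_w])) / span if n_snps else 0.0
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": end,
                    "n_snps": n_snps,
                    "fst": fst,
                    "pi_popA": pa,
                    "pi_popB": pb,
                    "pi_ratio": pi_ratio(pa, pb),
                    "low_support": n_snps < min_snps,
                }
            )
    return pd.DataFrame(rows)


def pi_ratio(pi_a: float, pi_b: float) -> float:
    """pi_A / pi_B; NaN (undefined) when pi_B is zero."""
    if pi_b == 0 or not np.isfinite(pi_b):
        return float("nan")
    return float(pi_a / pi_b)


def top_quantile_outliers(scores: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Mask of scores at or above the empirical (1-q) quantile.

    Ties at the threshold are included.  With fewer than 100 finite
    scores a 1% cut is not meaningful and a warning is emitted.
    """
    s = np.asarray(scores, dtype=float)
    finite = np.isfinite(s)
    if q >= 1:
        return finite.copy()
    if finite.sum() < 100:
        warnings.warn(
            f"only {int(finite.sum())} scored windows; top-{q:.0%} cut is weakly "
            "supported", stacklevel=2,
        )
    thr = np.quantile(s[finite], 1 - q)
    return finite & (s >= thr)


def intersect_candidates(
    sets: dict[str, set], k: int = 2
) -> tuple[set, dict[str, int]]:
    """At-least-k intersection plus Venn counts across candidate sets.

    Venn keys are '&'-joined method names for every non-empty combination,
    counting identifiers belonging to exactly that combination.
    """
    if not sets:
        raise ValueError("need at least one candidate set")
    names = list(sets)
    membership: dict[object, frozenset] = {}
    for name in names:
        for ident in sets[name]:
            membership.setdefault(ident, frozenset())
    for name in names:
        for ident in sets[name]:
            membership[ident] = membership[ident] | {name}
    venn: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = "&".join(combo)
            venn[key] = sum(1 for m in membership.values() if m == frozenset(combo))
    at_least_k = {ident for ident, m in membership.items() if len(m) >= k}
    return at_least_k, venn
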