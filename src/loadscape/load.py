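"""Population genetic-load statistics from polarized (derived) dosages.

Implements the relative derived-allele burden

    L_A,B(C) = sum_{i in C} f_iA (1 - f_iB)  /  sum_{j in I} f_jA (1 - f_jB)
    R_A/B(C) = L_A,B(C) / L_B,A(C)

where C is a class of protein-coding sites and I a set of intergenic
sites, with a 100-block positional jackknife for the standard error;
per-individual derived and homozygous-derived counts normalized by the
individual's derived synonymous count; and per-individual masked /
realized load in GERP units (heterozygous vs homozygous deleterious
derived alleles over called sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "derived_freqs",
    "l_ab",
    "r_ab",
    "per_individual_counts",
    "gerp_load",
    "group_ttest",
    "RJackknife",
]


def derived_freqs(dosage: np.ndarray, group_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site derived counts d, called allele counts n, and f = d/n.

    Missing genotypes (dosage < 0) contribute neither to d nor to n.
    Sites with n = 0 get f = NaN (flagged for exclusion by the caller).
    """
    g = dosage[group_mask]
    called = g >= 0
    n = 2 * called.sum(axis=0)
    d = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n > 0, d / np.maximum(n, 1), np.nan)
    return d, n, f


def l_ab(fA: np.ndarray, fB: np.ndarray, class_mask: np.ndarray, intergenic_mask: np.ndarray) -> float:
    """Class burden of A relative to B, normalized by intergenic sites.

    Returns NaN (with a warning) when the intergenic denominator is zero;
    never silently 0.
    """
    class_mask = np.asarray(class_mask, bool)
    intergenic_mask = np.asarray(intergenic_mask, bool)
    if not class_mask.any() or not intergenic_mask.any():
        raise ValueError("class and intergenic site sets must be non-empty")
    num = np.nansum(fA[class_mask] * (1 - fB[class_mask]))
    den = np.nansum(fA[intergenic_mask] * (1 - fB[intergenic_mask]))
    if den == 0:
        warnings.warn("intergenic normalization sum is zero; L undefined", stacklevel=2)
        return float("nan")
    return float(num / den)


@dataclass
class RJackknife:
    ratio: float
    sd: float
    n_blocks: int
    l_ab: float
    l_ba: float


def r_ab(
    fA: np.ndarray,
    fB: np.ndarray,
    class_mask: np.ndarray,
    intergenic_mask: np.ndarray,
    order: np.ndarray | None = None,
    n_blocks: int = 100,
) -> RJackknife:
    """R_A/B(C) with a delete-one positional block jackknife SD.

    ``order`` ranks sites by genome position (argsort of (chrom, pos));
    class and intergenic sites are blocked jointly in that order into
    ``n_blocks`` contiguous, equal-count blocks.  If fewer informative
    sites than blocks exist, the block count is reduced with a warning.
    """
    class_mask = np.asarray(class_mask, bool)
    intergenic_mask = np.asarray(intergenic_mask, bool)
    informative = (class_mask | intergenic_mask) & np.isfinite(fA) & np.isfinite(fB)
    c_ab = np.where(class_mask & informative, fA * (1 - fB), 0.0)
    c_ba = np.where(class_mask & informative, fB * (1 - fA), 0.0)
    i_ab = np.where(intergenic_mask & informative, fA * (1 - fB), 0.0)
    i_ba = np.where(intergenic_mask & informative, fB * (1 - fA), 0.0)

    S_cab, S_cba = c_ab.sum(), c_ba.sum()
    S_iab, S_iba = i_ab.sum(), i_ba.sum()
    if S_iab == 0 or S_iba == 0 or S_cba == 0:
        raise ValueError("R undefined: zero class or intergenic burden sum")
    ratio = (S_cab / S_iab) / (S_cba / S_iba)

    idx = np.flatnonzero(informative)
    if order is not None:
        rank = np.argsort(np.asarray(order)[idx], kind="stable")
        idx = idx[rank]
    b = min(n_blocks, idx.size)
    if b < n_blocks:
        warnings.warn(
            f"only {idx.size} informative sites; jackknife blocks reduced to {b}",
            stacklevel=2,
        )
    if b < 2:
        return RJackknife(ratio, 0.0, b, S_cab / S_iab, S_cba / S_iba)
    blocks = np.array_split(idx, b)
    reps = np.empty(b)
    for k, blk in enumerate(blocks):
        scab = S_cab - c_ab[blk].sum()
        scba = S_cba - c_ba[blk].sum()
        siab = S_iab - i_ab[blk].sum()
        siba = S_iba - i_ba[blk].sum()
        if siab == 0 or siba == 0 or scba == 0:
            reps[k] = ratio
        else:
            reps[k] = (scab / siab) / (scba / siba)
    sd = float(np.sqrt((b - 1) / b * np.sum((reps - reps.mean()) ** 2)))
    return RJackknife(float(ratio), sd, b, float(S_cab / S_iab), float(S_cba / S_iba))


def per_individual_counts(
    dosage: np.ndarray,
    class_masks: dict[str, np.ndarray],
    synonymous_mask: np.ndarray,
) -> pd.DataFrame:
    """Derived and homozygous-derived counts per individual per class.

    Both counts are divided by that individual's total derived synonymous
    count (the neutral yardstick); an individual with zero derived
    synonymous alleles gets NaN for every normalized column.
    """
    g = dosage
    called = g >= 0
    syn = np.asarray(synonymous_mask, bool)
    syn_derived = np.where(called[:, syn], g[:, syn], 0).sum(axis=1).astype(float)
    norm = np.where(syn_derived > 0, syn_derived, np.nan)
    out = {}
    for name, mask in class_masks.items():
        mask = np.asarray(mask, bool)
        sub = g[:, mask]
        csub = called[:, mask]
        total = np.where(csub, sub, 0).sum(axis=1)
        hom = 2 * np.where(csub, sub == 2, False).sum(axis=1)
        out[f"{name}_derived"] = total / norm
        out[f"{name}_hom_derived"] = hom / norm
    df = pd.DataFrame(out)
    df.insert(0, "syn_derived_count", syn_derived)
    return df


def gerp_load(
    dosage: np.ndarray,
    gerp: np.ndarray,
    deleterious_mask: np.ndarray,
    denominator: str = "per_individual",
) -> pd.DataFrame:
    """Masked and realized load per individual, in GERP units per site.

    masked   = sum of GERP over heterozygous deleterious derived sites
    realized = sum of GERP over homozygous deleterious derived sites

    both divided by the individual's count of called (non-missing)
    genotyped sites; ``denominator='genome'`` divides by the total site
    count instead.
    """
    if denominator not in ("per_individual", "genome"):
        raise ValueError("denominator must be 'per_individual' or 'genome'")
    g = dosage
    gerp = np.asarray(gerp, dtype=float)
    mask = np.asarray(deleterious_mask, bool)
    called = g >= 0
    n_called = called.sum(axis=1).astype(float)
    if np.any(n_called == 0):
        raise ValueError("individual with no called sites")
    den = n_called if denominator == "per_individual" else float(g.shape[1])
    w = np.where(mask, gerp, 0.0)
    masked = ((g == 1) * w).sum(axis=1) / den
    realized = ((g == 2) * w).sum(axis=1) / den
    return pd.DataFrame({"masked_load": masked, "realized_load": realized,
                         "n_called": n_called.astype(int)})


def group_ttest(values: np.ndarray, group_mask: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test (Welch) of a per-individual statistic between groups."""
    v = np.asarray(values, dtype=float)
    a, b = v[group_mask], v[~np.asarray(group_mask, bool)]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
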