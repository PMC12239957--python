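"""Ancestral-allele inference from outgroups and effect classification.

The ancestral allele at a site is the majority allele across the outgroup
columns; ties (and sites with no observed outgroup allele) are UNRESOLVED
and excluded downstream.  Genotypes are re-coded from ALT-allele dosage to
derived-allele dosage.  Missense deleteriousness uses the Grantham
physicochemical distance (range 5-215, radical at >= 150); site-level
deleteriousness uses a GERP rejected-substitutions threshold (default 4).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "UNRESOLVED",
    "GRANTHAM_DELETERIOUS",
    "GERP_DELETERIOUS",
    "infer_ancestral",
    "polarize",
    "classify_missense",
    "classify_gerp",
    "annotate_sites",
]

UNRESOLVED = "UNRESOLVED"
GRANTHAM_DELETERIOUS = 150
GERP_DELETERIOUS = 4.0
_MISSING = {".", "", "N", None}


def infer_ancestral(
    ref: np.ndarray, alt: np.ndarray, outgroups: list[np.ndarray]
) -> np.ndarray:
    """Majority-rule ancestral call per site from outgroup allele columns.

    Missing outgroup calls ('.') are ignored, so a single observed allele
    decides.  A strict tie, an allele outside {ref, alt}, or no observed
    allele at all yields UNRESOLVED (outgroup alleles matching neither
    REF nor ALT are treated as uninformative for a biallelic site and
    raise a malformed-input error only when non-nucleotide).
    """
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    n = ref.size
    votes_ref = np.zeros(n, dtype=int)
    votes_alt = np.zeros(n, dtype=int)
    valid = {"A", "C", "G", "T"}
    for og in outgroups:
        og = np.asarray(og, dtype=object)
        observed = ~np.isin(og, list(_MISSING))
        bad = observed & ~np.isin(og, list(valid))
        if np.any(bad):
            raise ValueError(
                f"malformed outgroup allele(s) {sorted(set(og[bad]))}; "
                "expected A/C/G/T or '.'"
            )
        votes_ref += (og == ref) & observed
        votes_alt += (og == alt) & observed
    anc = np.where(
        votes_ref > votes_alt, ref, np.where(votes_alt > votes_ref, alt, UNRESOLVED)
    )
    anc[(votes_ref == 0) & (votes_alt == 0)] = UNRESOLVED
    return anc


def polarize(
    genotypes: np.ndarray, ancestral: np.ndarray, ref: np.ndarray, alt: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert ALT dosage to derived dosage; return (dosage, excluded mask).

    Where the ancestral allele is ALT the dosage is flipped (2 - g);
    missing genotypes (-1) stay missing.  Columns whose ancestral call is
    UNRESOLVED are kept in place but reported in the excluded mask, with
    dosage set to missing so they cannot leak into statistics.
    """
    genotypes = np.asarray(genotypes)
    ancestral = np.asarray(ancestral, dtype=object)
    excluded = ancestral == UNRESOLVED
    flip = ancestral == np.asarray(alt, dtype=object)
    out = genotypes.astype(np.int8).copy()
    missing = genotypes < 0
    out[:, flip] = 2 - out[:, flip]
    out[missing] = -1
    out[:, excluded] = -1
    return out, excluded


def classify_missense(grantham, threshold: int = GRANTHAM_DELETERIOUS) -> np.ndarray:
    """Deleterious (radical) missense iff Grantham score >= threshold."""
    g = np.asarray(grantham, dtype=float)
    outside = np.isfinite(g) & ((g < 5) | (g > 215))
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} Grantham score(s) outside [5, 215]; "
            "classified by rule anyway",
            stacklevel=2,
        )
    return g >= threshold


def classify_gerp(gerp, threshold: float = GERP_DELETERIOUS) -> np.ndarray:
    """Site deleterious iff GERP (rejected substitutions) >= threshold."""
    return np.asarray(gerp, dtype=float) >= threshold


def annotate_sites(
    sites: pd.DataFrame,
    outgroup_cols: tuple[str, str] = ("aa1", "aa2"),
    grantham_threshold: int = GRANTHAM_DELETERIOUS,
    gerp_threshold: float = GERP_DELETERIOUS,
) -> pd.DataFrame:
    """Full annotation pass over a site table.

    Adds ``ancestral`` (allele or UNRESOLVED), ``deleterious_missense``
    (only defined for missense sites; False elsewhere) and
    ``gerp_deleterious`` columns.
    """
    out = sites.copy()
    out["ancestral"] = infer_ancestral(
        out["ref"].to_numpy(),
        out["alt"].to_numpy(),
        [out[c].to_numpy() for c in outgroup_cols],
    )
    is_missense = (out["effect_class"] == "missense").to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        deleterious = classify_missense(out["grantham"].to_numpy(), grantham_threshold)
    out["deleterious_missense"] = deleterious & is_missense
    out["gerp_deleterious"] = classify_gerp(out["gerp"].to_numpy(), gerp_threshold)
    return out


def polarize_result(sim_result, **annotate_kw):
    """Annotate + polarize a :class:`~loadscape.simulate.SimResult`.

    Returns (derived-dosage matrix over segregating sites, annotated
    segregating-site table with an ``excluded`` column).
    """
    seg = annotate_sites(sim_result.seg_sites, **annotate_kw)
    dosage, excluded = polarize(
        sim_result.genotypes,
        seg["ancestral"].to_numpy(),
        seg["ref"].to_numpy(),
        seg["alt"].to_numpy(),
    )
    seg = seg.copy()
    seg["excluded"] = excluded
    return dosage, seg
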