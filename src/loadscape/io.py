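"""File I/O: VCF (via cyvcf2 for reading), sample and annotation TSVs.

The VCF dialect carries the two outgroup alleles as INFO fields AA1/AA2;
polarized VCFs add the inferred ancestral allele as INFO field AA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_sample_table",
    "read_sample_table",
    "write_annotation",
    "read_annotation",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA1,Number=1,Type=String,Description="Outgroup 1 allele">
##INFO=<ID=AA2,Number=1,Type=String,Description="Outgroup 2 allele">
##INFO=<ID=AA,Number=1,Type=String,Description="Inferred ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    path: str | Path,
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    sample_ids: list[str],
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write ALT-dosage genotypes as a biallelic VCF.

    ``sites`` needs chrom, pos, ref, alt and optionally aa1/aa2/ancestral
    columns (emitted as INFO AA1/AA2/AA).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        has = {c: c in sites.columns for c in ("aa1", "aa2", "ancestral")}
        cols = sites[["chrom", "pos", "ref", "alt"]].to_numpy()
        for k in range(len(sites)):
            chrom, pos, ref, alt = cols[k]
            info = []
            if has["aa1"]:
                info.append(f"AA1={sites['aa1'].iat[k]}")
            if has["aa2"]:
                info.append(f"AA2={sites['aa2'].iat[k]}")
            if has["ancestral"]:
                info.append(f"AA={sites['ancestral'].iat[k]}")
            gts = "\t".join(_GT[int(g)] for g in genotypes[:, k])
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a biallelic VCF to (ALT dosage, site table, sample ids)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    genos = []
    for var in vcf:
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        genos.append(dosage.astype(np.int8))
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "aa1": var.INFO.get("AA1", "."),
                "aa2": var.INFO.get("AA2", "."),
                "ancestral": var.INFO.get("AA", None),
            }
        )
    sites = pd.DataFrame(rows)
    geno = np.column_stack(genos) if genos else np.empty((len(samples), 0), np.int8)
    return geno, sites, samples


def write_sample_table(path: str | Path, samples: pd.DataFrame) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotation(path: str | Path, sites: pd.DataFrame) -> None:
    """Annotation TSV: chrom, pos, effect class, Grantham, GERP (+ outgroups)."""
    cols = [c for c in ("chrom", "pos", "effect_class", "grantham", "gerp",
                        "aa1", "aa2", "segregating") if c in sites.columns]
    sites[cols].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
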