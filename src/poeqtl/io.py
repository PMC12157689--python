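"""File formats: VCF, PED pedigree, expression/covariate TSV, square GRM text.

The synthetic-data writers emit exactly the formats the pipeline reads,
so a simulated study round-trips through disk like a real one. VCF is
read with cyvcf2; output VCF is plain uncompressed text (GT only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "write_vcf", "read_vcf",
    "write_ped", "read_ped",
    "write_expression", "read_expression",
    "write_covariates", "read_covariates",
    "write_grm", "read_grm",
    "write_phased_vcf",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_GT_PHASED = {(0, 0): "0|0", (0, 1): "0|1", (1, 0): "1|0", (1, 1): "1|1"}


def _vcf_header(sample_ids, chrom):
    contigs = "".join(f"##contig=<ID={c}>\n" for c in pd.unique(np.asarray(chrom)))
    return (
        "##fileformat=VCFv4.2\n" + contigs +
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids) + "\n"
    )


def write_vcf(path, chrom, pos, snp_ids, genotypes: dict[str, np.ndarray]):
    """Unphased VCF; ``genotypes`` maps sample_id -> per-site alt counts."""
    samples = list(genotypes)
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, chrom))
        for j in range(len(pos)):
            gts = "\t".join(_GT[int(genotypes[s][j])] for s in samples)
            fh.write(f"{chrom[j]}\t{pos[j]}\t{snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_phased_vcf(path, chrom, pos, snp_ids,
                     haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]):
    """Phased VCF for children: GT is pipe-separated, paternal allele first."""
    samples = list(haplotypes)
    with open(path, "w") as fh:
        fh.write(_vcf_header(samples, chrom))
        for j in range(len(pos)):
            gts = "\t".join(
                _GT_PHASED[(int(haplotypes[s][0][j]), int(haplotypes[s][1][j]))]
                for s in samples)
            fh.write(f"{chrom[j]}\t{pos[j]}\t{snp_ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Returns (snp_table, genotypes dict sample -> int8 array)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, ids = [], [], []
    rows = []
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        g = var.gt_types.astype(np.int8)  # 0,1,2 and 3 for unknown
        g[g == 3] = -1
        rows.append(g)
    geno = np.array(rows).T if rows else np.empty((len(samples), 0), np.int8)
    snps = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss})
    return snps, {s: geno[i] for i, s in enumerate(samples)}


def write_ped(path, trios: list[tuple[str, str, str]],
              sexes: dict[str, int] | None = None):
    """PED-style pedigree: famID indID fatherID motherID sex (1=M, 2=F)."""
    with open(path, "w") as fh:
        for i, (father, mother, child) in enumerate(trios):
            fam = f"fam{i}"
            for ind, fa, mo, sex in (
                (father, "0", "0", 1), (mother, "0", "0", 2),
                (child, father, mother,
                 (sexes or {}).get(child, 0)),
            ):
                fh.write(f"{fam}\t{ind}\t{fa}\t{mo}\t{sex}\n")


def read_ped(path) -> list[tuple[str, str, str]]:
    """Returns the (father, mother, child) triples of a PED file."""
    ped = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fam", "ind", "father", "mother", "sex"])
    kids = ped[(ped["father"] != "0") & (ped["mother"] != "0")]
    return [(r.father, r.mother, r.ind) for r in kids.itertuples()]


def write_expression(path, tpm: pd.DataFrame):
    """Expression TSV: gene_id, chrom, tss, gc, then one column per child."""
    tpm.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_covariates(path, cov: pd.DataFrame):
    cov.to_csv(path, sep="\t", index_label="sample_id")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_grm(path, K: np.ndarray, sample_ids):
    """Whitespace-delimited square matrix with a sample-ID header line."""
    with open(path, "w") as fh:
        fh.write(" ".join(sample_ids) + "\n")
        for row in np.asarray(K, float):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_grm(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        ids = fh.readline().split()
        K = np.loadtxt(fh)
    if K.shape != (len(ids), len(ids)):
        raise ValueError("GRM is not square or does not match its header")
    return K, ids
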