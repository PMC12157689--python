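"""Genetic relatedness matrices and kinship-based trio discovery.

The GRM (twice the kinship matrix) used by the mixed model is a standard
centered-and-scaled genotype cross-product. Trio discovery exploits two
facts about kinship phi: a parent-offspring (PO) pair has phi = 0.25 on
*every* chromosome (one haplotype is shared identically by descent,
always), while full sibs have E[phi] = 0.25 but chromosome-to-chromosome
variation due to recombination. The per-chromosome SD of the kinship
estimate therefore separates PO pairs from sib pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_grm",
    "KinshipSummary",
    "kinship_summary",
    "find_trios",
]


def compute_grm(genotypes: np.ndarray, min_maf: float = 0.01) -> np.ndarray:
    """Centered-and-scaled genotype cross-product GRM (= 2 x kinship).

    ``genotypes`` is (n_samples, n_sites) of alt-allele counts. Sites with
    sample MAF below ``min_maf`` are dropped. K_ij = mean_m (g_im - 2 p_m)
    (g_jm - 2 p_m) / (2 p_m (1 - p_m)); positive semi-definite by
    construction.
    """
    g = np.asarray(genotypes, float)
    p = g.mean(axis=0) / 2.0
    keep = (p >= min_maf) & (p <= 1 - min_maf)
    if not keep.any():
        raise ValueError("no polymorphic sites for GRM")
    g = g[:, keep]
    p = p[keep]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    return z @ z.T / z.shape[1]


class KinshipSummary:
    """Per-pair mean and SD of per-chromosome kinship estimates."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray,
                 sample_ids: list[str]):
        self.mean = np.asarray(mean, float)
        self.sd = np.asarray(sd, float)
        self.sample_ids = list(sample_ids)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.sample_ids)
        rows = [
            {"a": self.sample_ids[i], "b": self.sample_ids[j],
             "phi_mean": self.mean[i, j], "phi_sd": self.sd[i, j]}
            for i in range(n) for j in range(i + 1, n)
        ]
        return pd.DataFrame(rows)


def kinship_summary(genotypes: np.ndarray, chrom: np.ndarray,
                    sample_ids: list[str] | None = None,
                    min_maf: float = 0.01) -> KinshipSummary:
    """Mean/SD across chromosomes of per-chromosome kinship (GRM / 2)."""
    chrom = np.asarray(chrom)
    chroms = pd.unique(chrom)
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes to compute a kinship SD")
    mats = []
    for c in chroms:
        K = compute_grm(genotypes[:, chrom == c], min_maf=min_maf)
        mats.append(K / 2.0)
    stack = np.stack(mats)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(genotypes.shape[0])]
    return KinshipSummary(stack.mean(axis=0), stack.std(axis=0, ddof=1),
                          sample_ids)


def find_trios(kin: KinshipSummary, t_unrel: float = 0.1,
               t_po: float = 0.1, sd_cut: float = 0.06
               ) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Trios (parentA, parentB, child) from kinship summaries.

    (A, B, C) qualifies when phi(A,B) < t_unrel, |phi(A,C) - 0.25| < t_po,
    |phi(B,C) - 0.25| < t_po, and both candidate PO pairs have
    per-chromosome SD < sd_cut (a sib pair mimics the PO mean but not the
    SD). A child matching more than one candidate parent pair is reported
    as ambiguous and skipped.

    Returns (trios, ambiguous_children).
    """
    n = len(kin.sample_ids)
    po = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(n):
            if i != j and abs(kin.mean[i, j] - 0.25) < t_po \
                    and kin.sd[i, j] < sd_cut:
                po[i, j] = True
    trios, ambiguous = [], []
    for c in range(n):
        parents = np.flatnonzero(po[c])
        pairs = [
            (a, b) for ii, a in enumerate(parents) for b in parents[ii + 1:]
            if abs(kin.mean[a, b]) < t_unrel
        ]
        if len(pairs) > 1:
            ambiguous.append(kin.sample_ids[c])
        elif len(pairs) == 1:
            a, b = pairs[0]
            trios.append((kin.sample_ids[a], kin.sample_ids[b],
                          kin.sample_ids[c]))
    return trios, ambiguous
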