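"""Cis-pair construction, eQTL classification, sentinels and gene sets.

Significant gene-SNP pairs are sorted into four mutually exclusive classes
(strict inequalities, secondary threshold theta, main threshold on the
log10 Bayes-factor scale, default 4):

    SP (paternal):  lgBF1 > 4  and lgBF0 < theta
    SM (maternal):  lgBF0 > 4  and lgBF1 < theta
    SO (opposing):  lgBFj - lgBFg > 4, lgBF1 > theta, lgBF0 > theta,
                    beta1 * beta0 < 0
    SG (genotype):  lgBFg > 4, lgBF1 > theta, lgBF0 > theta,
                    beta1 * beta0 > 0

For theta <= 4 the labels are mutually exclusive. Gene sets GP/GM/GA/GG
collect genes harboring at least one eQTL of each class; G1/G0/G2 are the
genes harboring exclusively paternal / maternal / opposing eQTL.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "THETA_DEFAULT",
    "cis_pairs",
    "classify",
    "classify_records",
    "sentinel",
    "sentinels_per_gene",
    "gene_sets",
    "poe_recoverable",
]

THETA_DEFAULT = float(np.log10(2.0))
BF_THRESHOLD = 4.0


def cis_pairs(genes: pd.DataFrame, snps: pd.DataFrame,
              window: int = 1_000_000) -> pd.DataFrame:
    """All (gene, SNP) pairs with |pos - tss| <= window on the same chromosome.

    ``genes`` needs columns gene_id, chrom, tss; ``snps`` needs snp_id,
    chrom, pos (1-based). The window is a closed interval; distance is to
    the TSS regardless of strand. Genes without any SNP in range simply
    contribute no pairs.
    """
    g = genes[["gene_id", "chrom", "tss"]]
    s = snps[["snp_id", "chrom", "pos"]]
    m = g.merge(s, on="chrom", how="inner")
    m["dist_tss"] = (m["pos"] - m["tss"]).abs()
    m = m[m["dist_tss"] <= window]
    return m[["gene_id", "snp_id", "chrom", "pos", "tss", "dist_tss"]] \
        .reset_index(drop=True)


def classify(lgBFg: float, lgBF1: float, lgBF0: float, lgBFj: float,
             beta1: float, beta0: float,
             theta: float = THETA_DEFAULT,
             bf_threshold: float = BF_THRESHOLD) -> str:
    """Label one record as SP, SM, SO, SG or none (strict inequalities).

    A record sitting exactly on theta satisfies neither the < nor the >
    branch and is labeled none.
    """
    if lgBF1 > bf_threshold and lgBF0 < theta:
        return "SP"
    if lgBF0 > bf_threshold and lgBF1 < theta:
        return "SM"
    if (lgBFj - lgBFg) > bf_threshold and lgBF1 > theta and lgBF0 > theta \
            and beta1 * beta0 < 0:
        return "SO"
    if lgBFg > bf_threshold and lgBF1 > theta and lgBF0 > theta \
            and beta1 * beta0 > 0:
        return "SG"
    return "none"


def classify_records(records: pd.DataFrame, theta: float = THETA_DEFAULT,
                     bf_threshold: float = BF_THRESHOLD) -> pd.DataFrame:
    """Vectorized classification; adds a ``label`` column."""
    r = records
    b1, b0 = r["lgBF1"].to_numpy(), r["lgBF0"].to_numpy()
    bg, bj = r["lgBFg"].to_numpy(), r["lgBFj"].to_numpy()
    prod = r["beta1"].to_numpy() * r["beta0"].to_numpy()
    label = np.full(len(r), "none", dtype=object)
    label[(bg > bf_threshold) & (b1 > theta) & (b0 > theta) & (prod > 0)] = "SG"
    label[((bj - bg) > bf_threshold) & (b1 > theta) & (b0 > theta) & (prod < 0)] = "SO"
    label[(b0 > bf_threshold) & (b1 < theta)] = "SM"
    label[(b1 > bf_threshold) & (b0 < theta)] = "SP"
    out = records.copy()
    out["label"] = label
    return out


def sentinel(records: pd.DataFrame) -> pd.Series:
    """The record with the largest lgBFj (one gene's records).

    Ties break by smaller |dist_tss| (when present), then lexicographic
    snp_id.
    """
    if records.empty:
        raise ValueError("sentinel of an empty record set")
    r = records.copy()
    keys = [("lgBFj", False)]
    if "dist_tss" in r.columns:
        keys.append(("dist_tss", True))
    keys.append(("snp_id", True))
    r = r.sort_values([k for k, _ in keys],
                      ascending=[a for _, a in keys],
                      kind="mergesort")
    return r.iloc[0]


def sentinels_per_gene(records: pd.DataFrame) -> pd.DataFrame:
    """Sentinel eQTL for every gene present in ``records``."""
    return records.groupby("gene_id", sort=True, group_keys=False) \
        .apply(sentinel, include_groups=False).reset_index()


def gene_sets(labeled: pd.DataFrame) -> dict[str, set]:
    """GP/GM/GA/GG and the exclusive sets G1/G0/G2 from labeled records."""
    def genes(lbl):
        return set(labeled.loc[labeled["label"] == lbl, "gene_id"])

    GP, GM, GA, GG = genes("SP"), genes("SM"), genes("SO"), genes("SG")
    return {
        "GP": GP, "GM": GM, "GA": GA, "GG": GG,
        "G1": GP - (GM | GA | GG),
        "G0": GM - (GP | GA | GG),
        "G2": GA - (GP | GM | GG),
    }


def poe_recoverable(records: pd.DataFrame,
                    bf_threshold: float = BF_THRESHOLD) -> pd.DataFrame:
    """Records invisible to the genotype test but significant under a POE test:
    lgBFg < 4 and (lgBF1 > 4 or lgBF0 > 4 or lgBFj > 4)."""
    r = records
    m = (r["lgBFg"] < bf_threshold) & (
        (r["lgBF1"] > bf_threshold) | (r["lgBF0"] > bf_threshold)
        | (r["lgBFj"] > bf_threshold))
    return r[m]
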