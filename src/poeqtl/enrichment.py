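"""Proportion tests and annotation/pleiotropy summaries over eQTL and gene sets.

Annotation flags (genic/intron/exon/ncRNA, GWAS-hit at 5e-8) and drug-target
catalogs are consumed as input tables; no external service is queried.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "prop_test_one_sample",
    "prop_test_two_sample",
    "pleiotropy_sets",
    "annotate_summary",
    "target_enrichment",
]

REGION_CLASSES = ("intron", "exon", "ncRNA", "other")


def prop_test_one_sample(k: int, n: int, f0: float,
                         side: str = "greater") -> tuple[float, float]:
    """One-sample test of a proportion against f0, normal approximation
    with continuity correction.

    The correction shrinks |k/n - f0| toward zero by 1/(2n), floored at
    zero (the convention of R's prop.test), then z = d_corr / sqrt(f0
    (1-f0)/n). Returns (f_hat, p). ``side`` is "greater", "less" or
    "two-sided".
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0 < f0 < 1:
        raise ValueError("f0 must be in (0, 1)")
    f_hat = k / n
    d = f_hat - f0
    d_corr = np.sign(d) * max(0.0, abs(d) - 1.0 / (2 * n))
    z = d_corr / np.sqrt(f0 * (1 - f0) / n)
    if side == "greater":
        p = stats.norm.sf(z)
    elif side == "less":
        p = stats.norm.cdf(z)
    elif side == "two-sided":
        p = min(1.0, 2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown side {side!r}")
    return float(f_hat), float(p)


def prop_test_two_sample(k1: int, n1: int, k2: int, n2: int,
                         side: str = "two-sided") -> float:
    """Pooled-variance z-test comparing two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0 if side != "two-sided" else 1.0
    z = (p1 - p2) / se
    if side == "greater":
        return float(stats.norm.sf(z))
    if side == "less":
        return float(stats.norm.cdf(z))
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))


def pleiotropy_sets(labeled: pd.DataFrame, annotation: pd.DataFrame | None = None,
                    k_max: int | None = None, label: str = "SG") -> pd.DataFrame:
    """Pk tables: SNPs of the given class that are eQTL of >= k eGenes.

    Returns one row per k with eQTL / SNP / eGene counts and, when an
    annotation table (indexed by snp_id with boolean flag columns) is
    given, the per-set fraction satisfying each flag. P1 is the full set;
    Pk is non-increasing in k.
    """
    r = labeled[labeled["label"] == label]
    per_snp = r.groupby("snp_id")["gene_id"].nunique()
    if per_snp.empty:
        return pd.DataFrame(columns=["k", "n_eqtl", "n_snp", "n_egene"])
    if k_max is None:
        k_max = int(per_snp.max())
    rows = []
    for k in range(1, k_max + 1):
        snps = set(per_snp[per_snp >= k].index)
        sub = r[r["snp_id"].isin(snps)]
        row = {"k": k, "n_eqtl": len(sub), "n_snp": len(snps),
               "n_egene": sub["gene_id"].nunique()}
        if annotation is not None and snps:
            ann = annotation.loc[sorted(snps)]
            for col in ann.columns:
                if ann[col].dtype == bool or set(ann[col].unique()) <= {0, 1}:
                    row[f"frac_{col}"] = float(ann[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_summary(labeled: pd.DataFrame, annotation: pd.DataFrame,
                     gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Per-class annotation summary (one row per label SO/SP/SM/SG).

    Counts eQTL (records), distinct SNPs and eGenes; medians of eGene
    length and |dist_tss|; fractions genic / per region class and the
    GWAS-hit fraction, all computed over *distinct SNPs*. SNPs missing
    from the annotation are excluded, with their count reported.
    """
    rows = []
    for lbl in ("SO", "SP", "SM", "SG"):
        sub = labeled[labeled["label"] == lbl]
        if sub.empty:
            continue
        snps = sub["snp_id"].unique()
        known = [s for s in snps if s in annotation.index]
        ann = annotation.loc[known]
        row = {
            "set": lbl,
            "n_eqtl": len(sub),
            "n_snp": len(snps),
            "n_egene": sub["gene_id"].nunique(),
            "n_snp_unannotated": len(snps) - len(known),
            "median_dist_tss": float(sub["dist_tss"].median())
            if "dist_tss" in sub.columns else np.nan,
        }
        if gene_lengths is not None:
            egenes = sub["gene_id"].unique()
            row["median_egene_len"] = float(
                gene_lengths.reindex(egenes).dropna().median())
        if len(known):
            if "genic" in ann.columns:
                row["frac_genic"] = float(ann["genic"].mean())
            if "region" in ann.columns:
                for rc in REGION_CLASSES:
                    row[f"frac_{rc}"] = float((ann["region"] == rc).mean())
            if "gwas_hit" in ann.columns:
                row["frac_gwas"] = float(ann["gwas_hit"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def target_enrichment(gene_sets_: dict[str, set], catalog: pd.DataFrame,
                      background_rates: dict[str, float],
                      n_tests: int = 12) -> pd.DataFrame:
    """Drug-target enrichment of eGene sets, one-sided proportion tests.

    ``catalog`` is indexed by gene_id with boolean columns (e.g.
    successful_target, clinical_trial_target, combined);
    ``background_rates`` maps each catalog column to its genome-wide
    target rate f0. Significance is Bonferroni-corrected over ``n_tests``.
    """
    rows = []
    for col, f0 in background_rates.items():
        flags = catalog[col]
        for name in ("GA", "GP", "GM", "GG"):
            genes = gene_sets_.get(name, set())
            if not genes:
                continue
            n = len(genes)
            k = int(flags.reindex(sorted(genes)).fillna(False).sum())
            f_hat, p = prop_test_one_sample(k, n, f0, side="greater")
            rows.append({
                "catalog": col, "set": name, "n_gene": n, "n_target": k,
                "f_hat": f_hat, "f0": f0, "p": p,
                "significant": p < 0.05 / n_tests,
            })
    return pd.DataFrame(rows)
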