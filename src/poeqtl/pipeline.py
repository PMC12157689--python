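"""End-to-end orchestration: files in, labeled eQTL and summaries out.

Stages: read trio VCF + pedigree -> Mendelian + HMM phasing -> expression
preparation -> four-way Bayes-factor association -> classification ->
gene sets and (optional) enrichment. Each stage is a library call and can
be run standalone on the previous stage's files; outputs are plain TSVs
plus a JSON run manifest, byte-identical under a fixed seed and inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .classify import (THETA_DEFAULT, cis_pairs, classify_records, gene_sets,
                       poe_recoverable, sentinels_per_gene)
from .expression import prepare_expression
from .lmm import PriorSpec, association_scan
from .phasing import phase_trio_dataset

log = logging.getLogger("poeqtl")

__all__ = ["PipelineConfig", "run_pipeline", "write_study"]


@dataclass
class PipelineConfig:
    """Inputs and thresholds of a pipeline run."""

    vcf: str
    ped: str
    expression: str
    covariates: str
    grm: str
    out_dir: str
    annotation: str | None = None
    targets: str | None = None
    cis_window: int = 1_000_000
    maf_min: float = 0.01
    theta: float = THETA_DEFAULT
    sigma: float = 0.5
    bf_threshold: float = 4.0
    max_zero_frac: float = 0.05
    hmm_rho: float = 0.005
    hmm_eps: float = 0.001
    max_panel: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.cis_window < 0:
            raise ValueError("cis_window must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self):
        for name in ("vcf", "ped", "expression", "covariates", "grm"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def write_study(study, out_dir) -> PipelineConfig:
    """Write a SyntheticStudy to disk in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = study.trios
    n = t.n_trios
    snp = t.snp_table()
    geno = {}
    trios = []
    for i in range(n):
        geno[f"F{i}"] = t.g_father[i]
        geno[f"M{i}"] = t.g_mother[i]
        geno[f"C{i}"] = t.g_child[i]
        trios.append((f"F{i}", f"M{i}", f"C{i}"))
    pio.write_vcf(out / "trios.vcf", snp["chrom"], snp["pos"], snp["snp_id"], geno)
    pio.write_ped(out / "trios.ped", trios)
    tpm = study.gene_meta[["chrom", "tss", "gc"]].join(study.tpm)
    pio.write_expression(out / "expression.tsv", tpm)
    pio.write_covariates(out / "covariates.tsv", study.covariates)
    pio.write_grm(out / "grm.txt", study.grm, list(study.covariates.index))
    with open(out / "sim_config.yaml", "w") as fh:
        cfg = {k: v for k, v in vars(study.config).items()
               if k != "effect_specs"}
        cfg["maf_range"] = list(study.config.maf_range)
        yaml.safe_dump(cfg, fh)
    return PipelineConfig(
        vcf=str(out / "trios.vcf"), ped=str(out / "trios.ped"),
        expression=str(out / "expression.tsv"),
        covariates=str(out / "covariates.tsv"), grm=str(out / "grm.txt"),
        out_dir=str(out / "results"), seed=study.config.seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of result DataFrames.

    Writes per-pair stats, labeled records, sentinel table, gene-set
    membership and a run manifest into ``config.out_dir``.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- stage: load genotypes and pedigree ---
    snps, geno = pio.read_vcf(config.vcf)
    trios = pio.read_ped(config.ped)
    log.info("loaded %d SNPs, %d trios", len(snps), len(trios))
    gF = np.stack([geno[f] for f, _, _ in trios])
    gM = np.stack([geno[m] for _, m, _ in trios])
    gC = np.stack([geno[c] for _, _, c in trios])
    children = [c for _, _, c in trios]

    # --- stage: phasing ---
    from .phasing import mendelian_error_mask

    counts["mendelian_errors"] = int(mendelian_error_mask(gF, gM, gC).sum())
    phased = phase_trio_dataset(
        gF, gM, gC, rho=config.hmm_rho, eps=config.hmm_eps,
        max_panel=config.max_panel, seed=config.seed)
    hap_pat = np.stack([p.h_pat for p in phased])
    hap_mat = np.stack([p.h_mat for p in phased])
    pio.write_phased_vcf(
        out / "phased.vcf", snps["chrom"], snps["pos"], snps["snp_id"],
        {c: (hap_pat[i], hap_mat[i]) for i, c in enumerate(children)})
    counts["triple_het_sites"] = int(
        sum((p.resolved_by != 0).sum() for p in phased))

    # --- stage: expression preparation ---
    tpm = pio.read_expression(config.expression)
    n_before = len(tpm)
    expr = prepare_expression(tpm, max_zero_frac=config.max_zero_frac)
    counts["genes_filtered"] = n_before - len(expr)
    log.info("expression: %d genes kept of %d", len(expr), n_before)

    # --- stage: association ---
    cov = pio.read_covariates(config.covariates)
    K, grm_ids = pio.read_grm(config.grm)
    order = [grm_ids.index(c) for c in children]
    K = K[np.ix_(order, order)]
    genes_df = expr.reset_index()[["gene_id", "chrom", "tss"]]
    pairs = cis_pairs(genes_df, snps, window=config.cis_window)
    counts["cis_pairs"] = len(pairs)
    stats = association_scan(
        expr[[c for c in expr.columns if c in ("chrom", "tss", "gc")]
             + children],
        hap_pat, hap_mat, snps, cov.loc[children], K,
        pairs[["gene_id", "snp_id"]],
        prior=PriorSpec(sigma=config.sigma), maf_min=config.maf_min)
    counts["pairs_tested"] = len(stats)
    stats.to_csv(out / "assoc_stats.tsv", sep="\t", index=False,
                 float_format="%.6g")

    # --- stage: classification ---
    labeled = classify_records(stats, theta=config.theta,
                               bf_threshold=config.bf_threshold)
    labeled.to_csv(out / "labeled_eqtl.tsv", sep="\t", index=False,
                   float_format="%.6g")
    sig = labeled[labeled["label"] != "none"]
    sent = sentinels_per_gene(stats) if len(stats) else pd.DataFrame()
    sent.to_csv(out / "sentinels.tsv", sep="\t", index=False,
                float_format="%.6g")
    sets = gene_sets(labeled)
    with open(out / "gene_sets.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in sets.items()}, fh, indent=1)
    recover = poe_recoverable(stats, bf_threshold=config.bf_threshold)
    counts.update({
        "significant_eqtl": len(sig),
        "poe_recoverable": len(recover),
        **{f"n_{k}": len(v) for k, v in sets.items()},
    })

    # --- manifest ---
    from . import __version__

    manifest = {
        "package": "poeqtl", "version": __version__, "seed": config.seed,
        "thresholds": {"bf": config.bf_threshold, "theta": config.theta,
                       "maf_min": config.maf_min, "sigma": config.sigma,
                       "cis_window": config.cis_window},
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("pipeline complete: %s", counts)
    return {"stats": stats, "labeled": labeled, "sentinels": sent,
            "gene_sets": sets, "manifest": manifest}
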