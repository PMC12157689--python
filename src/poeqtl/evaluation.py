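"""Truth-based evaluation experiments on synthetic data.

These run the actual pipeline stages against the generator's recorded
truth: triple-heterozygote phasing accuracy, difference-test null
calibration, and recovery of planted paternal/maternal/opposing/genotype
effects (modal class label and credible-interval coverage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import classify_records
from .expression import prepare_expression
from .lmm import EigenGRM, association_scan, bf_joint
from .phasing import UNRESOLVED, mendelian_phase, phase_trio_dataset
from .simulate import (EffectSpec, SimConfig, simulate_panel,
                       simulate_study, simulate_trios)

__all__ = [
    "phasing_accuracy_experiment",
    "diff_test_calibration_experiment",
    "planted_recovery_experiment",
]


def phasing_accuracy_experiment(n_trios: int = 200, n_sites: int = 5000,
                                seed: int = 11) -> dict:
    """Triple-het phasing error of the full mask-and-impute pipeline.

    Returns the error rate (per triple-het site, paternal/maternal
    assignment vs transmitted truth) and the site count.
    """
    cfg = SimConfig(n_trios=n_trios, n_sites=n_sites, seed=seed)
    rng = np.random.default_rng(seed)
    panel = simulate_panel(cfg, rng)
    trios = simulate_trios(panel, cfg, rng)
    phased = phase_trio_dataset(trios.g_father, trios.g_mother,
                                trios.g_child, seed=seed + 1)
    errs = tot = 0
    for i, p in enumerate(phased):
        m = mendelian_phase(trios.g_father[i], trios.g_mother[i],
                            trios.g_child[i])
        triple = m.resolved_by == UNRESOLVED
        tot += int(triple.sum())
        errs += int((p.h_pat[triple]
                     != trios.truth.child_pat[i][triple]).sum())
    return {"error_rate": errs / tot if tot else np.nan,
            "n_triple_het": tot, "n_errors": errs}


def diff_test_calibration_experiment(n_genes: int = 2000, n: int = 1000,
                                     seed: int = 404,
                                     alpha: float = 0.05) -> dict:
    """Fraction of null (beta1 = beta0) genes rejected by the POE
    difference test at level alpha."""
    rng = np.random.default_rng(seed)
    W = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    grm = EigenGRM(np.eye(n))
    ps = np.empty(n_genes)
    for i in range(n_genes):
        x1 = rng.integers(0, 2, n).astype(float)
        x0 = rng.integers(0, 2, n).astype(float)
        b = rng.uniform(0.2, 0.8)
        y = b * x1 + b * x0 + rng.normal(size=n)
        ps[i] = bf_joint(y, W, x1, x0, grm, 0.0).p_diff
    return {"rejection_rate": float((ps < alpha).mean()),
            "n_genes": n_genes, "alpha": alpha,
            "p_values": ps}


def _recovery_effect_specs(per_class: int, rng: np.random.Generator,
                           min_beta: float = 0.75, max_beta: float = 1.5,
                           n_null: int | None = None):
    """Balanced effect specs: per_class genes of each non-null class plus
    null genes. The null block also keeps the per-sample GC smoother's
    per-gene leverage realistically small (a real transcriptome has
    thousands of genes; a smoother fitted over only a handful would
    absorb part of each gene's own signal)."""
    if n_null is None:
        n_null = per_class
    specs = []
    for _ in range(per_class):
        b = float(rng.uniform(min_beta, max_beta))
        specs.append(EffectSpec("paternal", beta1=b * rng.choice([-1, 1])))
    for _ in range(per_class):
        b = float(rng.uniform(min_beta, max_beta))
        specs.append(EffectSpec("maternal", beta0=b * rng.choice([-1, 1])))
    for _ in range(per_class):
        b = float(rng.uniform(min_beta, max_beta)) * rng.choice([-1, 1])
        b2 = -float(rng.uniform(min_beta, max_beta)) * np.sign(b)
        specs.append(EffectSpec("opposing", beta1=b, beta0=b2))
    for _ in range(per_class):
        b = float(rng.uniform(min_beta, max_beta)) * rng.choice([-1, 1])
        specs.append(EffectSpec("genotype", beta1=b, beta0=b))
    for _ in range(n_null):
        specs.append(EffectSpec("null"))
    return tuple(specs)


def planted_recovery_experiment(n_trios: int = 1000, n_sites: int = 600,
                                per_class: int = 12, n_null: int = 132,
                                seed: int = 2718,
                                theta: float | None = None) -> dict:
    """End-to-end recovery of planted eQTL classes.

    Simulates trios, phases children with the HMM pipeline (no access to
    true phase), prepares expression, runs the four-way Bayes-factor scan
    at each gene's causal SNP, classifies, and compares with truth.

    Returns per-class modal labels, the confusion table, and the coverage
    of the 95% posterior intervals for (beta1, beta0) against the
    standardized truth (true beta divided by the latent phenotype SD --
    the estimand after rank-normalization).
    """
    from .classify import THETA_DEFAULT

    if theta is None:
        theta = THETA_DEFAULT
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_trios=n_trios, n_sites=n_sites,
                    n_genes=4 * per_class + n_null,
                    effect_specs=_recovery_effect_specs(per_class, rng,
                                                        n_null=n_null),
                    seed=seed)
    study = simulate_study(cfg)
    t = study.trios

    phased = phase_trio_dataset(t.g_father, t.g_mother, t.g_child,
                                seed=seed + 1)
    hap_pat = np.stack([p.h_pat for p in phased])
    hap_mat = np.stack([p.h_mat for p in phased])

    tpm = study.gene_meta[["chrom", "tss", "gc"]].join(study.tpm)
    expr = prepare_expression(tpm)
    snps = t.snp_table()

    # evaluate at each gene's causal SNP (the planted eQTL)
    pairs = pd.DataFrame({
        "gene_id": study.gene_meta.index,
        "snp_id": [f"snp{s}" for s in study.gene_meta["causal_site"]],
    })
    stats = association_scan(expr, hap_pat, hap_mat, snps,
                             study.covariates, study.grm, pairs)
    labeled = classify_records(stats, theta=theta).set_index("gene_id")

    truth = study.gene_meta
    label_map = {"paternal": "SP", "maternal": "SM", "opposing": "SO",
                 "genotype": "SG", "null": "none"}
    rows, cover_events = [], []
    for gene_id, tr in truth.iterrows():
        if gene_id not in labeled.index:
            continue
        r = labeled.loc[gene_id]
        sd = tr["latent_sd"]
        if tr["true_kind"] != "null":
            # coverage assessed on the planted-effect genes, against the
            # standardized truth (the estimand after rank-normalization)
            for bhat, se, btrue in ((r["beta1"], r["se1"], tr["true_beta1"]),
                                    (r["beta0"], r["se0"], tr["true_beta0"])):
                cover_events.append(
                    abs(bhat - btrue / sd) <= 1.959964 * se)
        rows.append({"gene_id": gene_id, "true_kind": tr["true_kind"],
                     "expected_label": label_map[tr["true_kind"]],
                     "label": r["label"]})
    table = pd.DataFrame(rows)
    modal = (table.groupby("true_kind")["label"]
             .agg(lambda s: s.mode().iloc[0]).to_dict())
    confusion = pd.crosstab(table["true_kind"], table["label"])
    correct = (table["label"] == table["expected_label"])
    per_class_acc = correct.groupby(table["true_kind"]).mean().to_dict()
    return {
        "modal_labels": modal,
        "expected_modal": {k: label_map[k] for k in modal},
        "confusion": confusion,
        "accuracy_by_class": per_class_acc,
        "coverage_95": float(np.mean(cover_events)),
        "n_coverage_events": len(cover_events),
        "n_genes": len(table),
        "stats": stats,
    }
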