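"""Synthetic trio genotype + expression data with known truth.

Emulates the statistical structure of a family-based whole-blood eQTL
study: LD-structured founder haplotypes (a Li-Stephens-style copying
mosaic over a small seed set), Mendelian transmission with recombination,
rare genotype errors injected into parents, and gene expression driven by
paternal/maternal haplotype effects plus a polygenic random effect whose
covariance is proportional to a genetic relatedness matrix (GRM).

Every quantity the analysis pipeline later estimates (phase, effect sizes,
eQTL class labels) has a recorded truth value in :class:`SimTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "EffectSpec",
    "SimConfig",
    "SimTruth",
    "Panel",
    "TrioDataset",
    "default_effect_specs",
    "default_gc_bias",
    "simulate_panel",
    "simulate_trios",
    "simulate_covariates",
    "simulate_expression",
    "simulate_study",
]

EFFECT_KINDS = ("null", "paternal", "maternal", "opposing", "genotype")


@dataclass(frozen=True)
class EffectSpec:
    """Planted cis effect for one gene.

    ``beta1`` is the paternal-allele effect, ``beta0`` the maternal-allele
    effect, both in units of the residual (phenotype) SD of the latent
    log-expression. ``opposing`` requires beta1*beta0 < 0 and ``genotype``
    requires beta1 == beta0.
    """

    kind: str = "null"
    beta1: float = 0.0
    beta0: float = 0.0

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "null" and (self.beta1 != 0 or self.beta0 != 0):
            raise ValueError("null effect must have beta1 = beta0 = 0")
        if self.kind == "paternal" and self.beta1 == 0:
            raise ValueError("paternal effect requires beta1 != 0")
        if self.kind == "maternal" and self.beta0 == 0:
            raise ValueError("maternal effect requires beta0 != 0")
        if self.kind == "opposing" and not self.beta1 * self.beta0 < 0:
            raise ValueError("opposing effect requires beta1 * beta0 < 0")
        if self.kind == "genotype" and self.beta1 != self.beta0:
            raise ValueError("genotype effect requires beta1 == beta0")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions used throughout the test-suite:
    haplotype-block LD from a copying mosaic (switch rate 0.003 per
    adjacent-site interval, i.e. block scale ~300 kb at 1 kb spacing) over
    a 12-haplotype seed set related by a copy-and-mutate genealogy
    (pairwise divergence ~``seed_divergence``); meiotic crossovers at the
    human genetic-map scale (~1.3 cM/Mb); common variants; the
    Mendelian-error rate of 4.76 per 100,000 SNPs per trio reported for
    deep-sequenced trio data; and a polygenic component with variance
    ratio eta = 0.5 relative to the unit residual (tau = 1).
    """

    n_trios: int = 300
    n_sites: int = 2000
    n_genes: int = 50
    panel_size: int = 120
    n_seed_haplotypes: int = 12
    seed_divergence: float = 0.3
    recomb_rate: float = 0.003
    meiosis_recomb_rate: float = 1.3e-5
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotype_error_rate: float = 4.76e-5
    eta: float = 0.5
    tau: float = 1.0
    effect_specs: tuple[EffectSpec, ...] | None = None
    zero_inflation: float = 0.0
    n_grm_sites: int = 2000
    n_chromosomes: int = 1
    site_spacing_bp: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("n_trios", "n_sites", "n_genes", "panel_size",
                     "n_seed_haplotypes", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("recomb_rate", "meiosis_recomb_rate", "seed_divergence",
                     "genotype_error_rate", "zero_inflation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a closed interval in (0, 0.5]")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.effect_specs is not None and len(self.effect_specs) != self.n_genes:
            raise ValueError("effect_specs must have one entry per gene")


@dataclass
class SimTruth:
    """Ground truth recorded by the generator."""

    # (n_trios, n_sites) transmitted haplotypes of each child
    child_pat: np.ndarray
    child_mat: np.ndarray
    # list of (trio_index, site_index, parent) injected genotype errors;
    # parent is 0 for father, 1 for mother
    error_sites: list[tuple[int, int, int]]
    allele_freqs: np.ndarray  # per-site panel alt-allele frequency
    # filled by simulate_expression
    effects: pd.DataFrame | None = None  # per-gene kind, beta1, beta0, causal site
    latent_sd: np.ndarray | None = None  # per-gene SD of the latent phenotype


@dataclass
class Panel:
    """Phased founder haplotypes (H x S, 0/1) with site metadata."""

    haplotypes: np.ndarray
    positions: np.ndarray  # 1-based bp, strictly increasing per chromosome
    chrom: np.ndarray      # chromosome name per site

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class TrioDataset:
    """Unphased genotypes for a set of trios over common sites."""

    g_father: np.ndarray  # (n_trios, n_sites) int8, alt-allele counts
    g_mother: np.ndarray
    g_child: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    truth: SimTruth
    extra_children: np.ndarray | None = None  # optional sibs, for kinship tests

    @property
    def n_trios(self) -> int:
        return self.g_child.shape[0]

    @property
    def n_sites(self) -> int:
        return self.g_child.shape[1]

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": [f"snp{i}" for i in range(self.n_sites)],
            "chrom": self.chrom,
            "pos": self.positions,
        })


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Smooth additive log-expression bias as a function of GC fraction.

    A concave bump peaking near GC = 0.45, qualitatively matching the
    GC-content bias curves seen in RNAseq library preparations.
    """
    gc = np.asarray(gc, float)
    return 1.2 * gc - 3.0 * (gc - 0.45) ** 2


def default_effect_specs(n_genes: int, rng: np.random.Generator) -> tuple[EffectSpec, ...]:
    """Default per-gene effect mix: mostly null, a genotype-eQTL block, and
    smaller paternal/maternal/opposing blocks, echoing the relative abundance
    of eQTL classes in blood (genotype >> imprinting > opposing)."""
    specs: list[EffectSpec] = []
    kinds = rng.choice(
        EFFECT_KINDS, size=n_genes, p=[0.50, 0.08, 0.08, 0.04, 0.30]
    )
    for kind in kinds:
        b = float(rng.uniform(0.75, 1.5)) * (1 if rng.random() < 0.5 else -1)
        if kind == "null":
            specs.append(EffectSpec("null"))
        elif kind == "paternal":
            specs.append(EffectSpec("paternal", beta1=b))
        elif kind == "maternal":
            specs.append(EffectSpec("maternal", beta0=b))
        elif kind == "opposing":
            b2 = -float(rng.uniform(0.75, 1.5)) * np.sign(b)
            specs.append(EffectSpec("opposing", beta1=b, beta0=b2))
        else:
            specs.append(EffectSpec("genotype", beta1=b, beta0=b))
    return tuple(specs)


def _site_chromosomes(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Assign sites to chromosomes in contiguous blocks with 1-based positions."""
    sizes = np.full(config.n_chromosomes, config.n_sites // config.n_chromosomes)
    sizes[: config.n_sites % config.n_chromosomes] += 1
    chrom = np.concatenate([
        np.full(s, f"chr{i + 1}") for i, s in enumerate(sizes)
    ])
    pos = np.concatenate([
        (np.arange(s) + 1) * config.site_spacing_bp for s in sizes
    ])
    return chrom, pos


def _mosaic_paths(rng, n_hap, n_sites, n_sources, rate, chrom_breaks):
    """Copying paths over sources: switch w.p. `rate` per interval (uniform
    over sources, including self); independent restart at chromosome breaks."""
    paths = np.empty((n_hap, n_sites), dtype=np.int64)
    paths[:, 0] = rng.integers(0, n_sources, n_hap)
    switches = rng.random((n_hap, n_sites - 1)) < rate
    draws = rng.integers(0, n_sources, (n_hap, n_sites - 1))
    for j in range(1, n_sites):
        s = switches[:, j - 1] | chrom_breaks[j - 1]
        paths[:, j] = np.where(s, draws[:, j - 1], paths[:, j - 1])
    return paths


def simulate_panel(config: SimConfig, rng: np.random.Generator | None = None,
                   max_retries: int = 100) -> Panel:
    """LD-structured founder haplotype panel.

    A small set of seed haplotypes related by a copy-and-mutate genealogy
    (seed j copies a random earlier seed, flipping each allele with
    probability ``seed_divergence``; seed 0 is drawn site-independently
    with alt frequencies uniform in ``maf_range``). Panel haplotypes copy
    from the seeds through a Markov mosaic with switch probability
    ``recomb_rate`` per adjacent-site interval, which induces tunable,
    block-like LD with locally similar templates. Sites whose panel minor
    allele frequency falls outside ``maf_range`` have their seed column
    redrawn (genealogy and copying paths fixed); after ``max_retries``
    rounds an unsatisfiable range raises ``RuntimeError``.
    """
    if config.panel_size < 2:
        raise ValueError("panel_size must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom, pos = _site_chromosomes(config)
    breaks = chrom[1:] != chrom[:-1]
    lo, hi = config.maf_range
    k, S = config.n_seed_haplotypes, config.n_sites

    parent = np.array([0] + [int(rng.integers(0, j)) for j in range(1, k)])

    def draw_columns(cols: np.ndarray) -> np.ndarray:
        f = rng.uniform(lo, hi, len(cols))
        s = np.empty((k, len(cols)), np.int8)
        s[0] = rng.random(len(cols)) < f
        for j in range(1, k):
            flip = rng.random(len(cols)) < config.seed_divergence
            s[j] = np.where(flip, 1 - s[parent[j]], s[parent[j]])
        return s

    seeds = draw_columns(np.arange(S))
    paths = _mosaic_paths(rng, config.panel_size, S, k, config.recomb_rate, breaks)
    hap = np.take_along_axis(seeds, paths, axis=0).astype(np.int8)

    for _ in range(max_retries):
        maf = np.minimum(hap.mean(axis=0), 1 - hap.mean(axis=0))
        bad = (maf < lo - 1e-12) | (maf > hi + 1e-12)
        if not bad.any():
            return Panel(hap, pos, chrom)
        cols = np.flatnonzero(bad)
        seeds[:, cols] = draw_columns(cols)
        hap[:, cols] = np.take_along_axis(seeds[:, cols], paths[:, cols], axis=0)
    raise RuntimeError(
        f"could not satisfy maf_range={config.maf_range} after {max_retries} "
        "redraw rounds; range too narrow for this panel size"
    )


# Mendelian compatibility: possible child genotype given parent genotypes
_CHILD_OK = {  # (gF, gM) -> set of compatible child genotypes
    (f, m): {a + b for a in ({0} if f == 0 else {1} if f == 2 else {0, 1})
             for b in ({0} if m == 0 else {1} if m == 2 else {0, 1})}
    for f in (0, 1, 2) for m in (0, 1, 2)
}


def _recombine(rng, h_a, h_b, rate, breaks):
    """One gamete per row-pair: copy from h_a/h_b switching w.p. rate."""
    n, S = h_a.shape
    state = rng.integers(0, 2, (n, 1)).astype(bool)
    if S > 1:
        sw = rng.random((n, S - 1)) < rate
        sw = sw | breaks[None, :]
        state = np.concatenate([state, sw], axis=1)
        state = np.cumsum(state, axis=1) % 2 == 1
    else:
        state = state
    return np.where(state, h_b, h_a).astype(np.int8)


def simulate_trios(panel: Panel, config: SimConfig,
                   rng: np.random.Generator | None = None,
                   n_extra_children: int = 0) -> TrioDataset:
    """Draw trios from the panel and inject rare parental genotype errors.

    Each parental haplotype is a fresh copying mosaic over the panel
    (population-scale switch rate ``recomb_rate``); each child inherits
    one recombinant gamete per parent, with crossovers at the meiotic
    rate ``meiosis_recomb_rate`` per interval. Genotype errors are
    injected into
    parents only, at ``genotype_error_rate`` per SNP per trio, and are
    placed so that they create a Mendelian incompatibility (detectable);
    sites where a single-parent corruption cannot do so are resampled.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, S = config.n_trios, panel.n_sites
    H = panel.n_haplotypes
    breaks = panel.chrom[1:] != panel.chrom[:-1]

    def parent_haps(count):
        paths = _mosaic_paths(rng, count, S, H, config.recomb_rate, breaks)
        return np.take_along_axis(panel.haplotypes, paths, axis=0).astype(np.int8)

    f1, f2 = parent_haps(n), parent_haps(n)
    m1, m2 = parent_haps(n), parent_haps(n)
    child_pat = _recombine(rng, f1, f2, config.meiosis_recomb_rate, breaks)
    child_mat = _recombine(rng, m1, m2, config.meiosis_recomb_rate, breaks)

    gF = (f1 + f2).astype(np.int8)
    gM = (m1 + m2).astype(np.int8)
    gC = (child_pat + child_mat).astype(np.int8)

    extra = None
    if n_extra_children > 0:
        sibs = []
        for _ in range(n_extra_children):
            sp = _recombine(rng, f1, f2, config.meiosis_recomb_rate, breaks)
            sm = _recombine(rng, m1, m2, config.meiosis_recomb_rate, breaks)
            sibs.append((sp + sm).astype(np.int8))
        extra = np.stack(sibs)

    # --- error injection (parents only, detectable) ---
    errors: list[tuple[int, int, int]] = []
    n_err = rng.binomial(n * S, config.genotype_error_rate)
    attempts = 0
    while len(errors) < n_err and attempts < 50 * (n_err + 1):
        attempts += 1
        flat = rng.integers(0, n * S)
        i, j = divmod(int(flat), S)
        parent_order = rng.permutation(2)
        placed = False
        for which in parent_order:
            own = gF[i, j] if which == 0 else gM[i, j]
            other = gM[i, j] if which == 0 else gF[i, j]
            vals = [v for v in rng.permutation(3) if v != own]
            for v in vals:
                pair = (v, other) if which == 0 else (other, v)
                if gC[i, j] not in _CHILD_OK[pair]:
                    if which == 0:
                        gF[i, j] = v
                    else:
                        gM[i, j] = v
                    errors.append((i, j, int(which)))
                    placed = True
                    break
            if placed:
                break

    truth = SimTruth(
        child_pat=child_pat, child_mat=child_mat, error_sites=errors,
        allele_freqs=panel.allele_freqs(),
    )
    return TrioDataset(gF, gM, gC, panel.positions, panel.chrom, truth,
                       extra_children=extra)


# default covariate coefficients a: intercept-free, applied to standardized
# covariates so that each contributes comparably to the latent phenotype
_DEFAULT_COVARIATE_COEF = {
    "age": 0.2, "sex": 0.3, "bmi": 0.15,
    "neut": 0.2, "lymph": -0.15, "mono": 0.1, "eos": 0.05,
}


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Age/sex/BMI and white-cell composition fractions for n children."""
    df = pd.DataFrame({
        "age": rng.normal(45.0, 12.0, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "bmi": rng.normal(27.0, 4.5, n),
        "neut": np.clip(rng.normal(0.58, 0.08, n), 0.2, 0.9),
        "lymph": np.clip(rng.normal(0.30, 0.07, n), 0.05, 0.6),
        "mono": np.clip(rng.normal(0.07, 0.02, n), 0.01, 0.2),
        "eos": np.clip(rng.normal(0.03, 0.015, n), 0.0, 0.15),
    })
    df.index = [f"C{i}" for i in range(n)]
    return df


def _check_psd(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    K = np.asarray(K, float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("GRM must be a symmetric square matrix")
    w, V = np.linalg.eigh(K)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError("GRM is not positive semi-definite")
    return V @ (np.clip(w, 0, None)[:, None] * V.T)


def simulate_expression(
    child_pat: np.ndarray,
    child_mat: np.ndarray,
    covariates: pd.DataFrame,
    K: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = default_gc_bias,
    snp_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM-like expression with planted cis effects and a polygenic term.

    The latent phenotype of gene g is

        y = W a + x1 beta1 + x0 beta0 + u + e,
        u ~ MVN(0, eta/tau * K),  e ~ MVN(0, 1/tau * I),

    where x1/x0 are the paternal/maternal alleles at the gene's causal SNP.
    Emitted TPM = exp(y + gc_bias(GC)); the downstream analysis only uses
    ranks of log(1+TPM), so any monotone emission is equivalent.

    Returns ``(tpm, meta)``: genes x samples TPM values, and per-gene
    metadata (chrom, tss, gc, truth effect columns). Truth is also appended
    to ``config``-independent columns of ``meta`` (kind, beta1, beta0,
    causal_snp, latent_sd).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n, S = child_pat.shape
    K = _check_psd(K)
    if K.shape[0] != n:
        raise ValueError("GRM dimension must equal the number of children")

    specs = config.effect_specs
    if specs is None:
        specs = default_effect_specs(config.n_genes, rng)

    cov = covariates.copy()
    Wstd = (cov - cov.mean()) / cov.std().replace(0.0, 1.0)
    a = np.array([_DEFAULT_COVARIATE_COEF.get(c, 0.1) for c in cov.columns])
    fixed_cov = Wstd.to_numpy() @ a

    # polygenic component, shared Cholesky-like factor via eigh
    w, V = np.linalg.eigh(K)
    L = V * np.sqrt(np.clip(w, 0, None))
    sd_e = 1.0 / np.sqrt(config.tau)
    sd_u = np.sqrt(config.eta / config.tau)

    if snp_table is None:
        chrom = np.array(["chr1"] * S)
        positions = (np.arange(S) + 1) * config.site_spacing_bp
    else:
        chrom = snp_table["chrom"].to_numpy()
        positions = snp_table["pos"].to_numpy()

    # candidate causal sites: common in the children
    dose = (child_pat + child_mat).mean(axis=0) / 2.0
    maf = np.minimum(dose, 1 - dose)
    common = np.flatnonzero(maf >= 0.1)
    if common.size == 0:
        common = np.arange(S)

    gene_ids = [f"gene{i}" for i in range(config.n_genes)]
    tpm = np.empty((config.n_genes, n))
    rows = []
    gcs = rng.uniform(0.3, 0.7, config.n_genes)
    for gi, spec in enumerate(specs):
        site = int(rng.choice(common))
        x1 = child_pat[:, site].astype(float)
        x0 = child_mat[:, site].astype(float)
        u = L @ rng.normal(0, sd_u, n)
        e = rng.normal(0, sd_e, n)
        y = fixed_cov + spec.beta1 * x1 + spec.beta0 * x0 + u + e
        bias = float(gc_bias(np.array([gcs[gi]]))[0]) if gc_bias is not None else 0.0
        t = np.exp(y + bias)
        if config.zero_inflation > 0:
            t = np.where(rng.random(n) < config.zero_inflation, 0.0, t)
        tpm[gi] = t
        rows.append({
            "gene_id": gene_ids[gi], "chrom": chrom[site],
            "tss": int(positions[site]), "gc": gcs[gi],
            "true_kind": spec.kind, "true_beta1": spec.beta1,
            "true_beta0": spec.beta0, "causal_site": site,
            "latent_sd": float(np.std(y)),
        })

    meta = pd.DataFrame(rows).set_index("gene_id")
    tpm_df = pd.DataFrame(tpm, index=gene_ids, columns=covariates.index)
    return tpm_df, meta


@dataclass
class SyntheticStudy:
    """A full synthetic dataset: genotypes, phase truth, expression, GRM."""

    config: SimConfig
    panel: Panel
    trios: TrioDataset
    covariates: pd.DataFrame
    grm: np.ndarray           # 2 x kinship of the children
    tpm: pd.DataFrame         # genes x children
    gene_meta: pd.DataFrame   # chrom/tss/gc + truth columns


def simulate_unlinked_genotypes(n_samples: int, n_sites: int,
                                maf_range: tuple[float, float],
                                rng: np.random.Generator) -> np.ndarray:
    """Genome-wide unlinked markers for relatedness estimation.

    Stands in for the SNPs outside the simulated cis region: founders are
    unrelated, sites are in linkage equilibrium, so the resulting GRM of
    the children is near-identity with O(1/sqrt(M)) sampling noise --
    the regime of a GRM computed from millions of genome-wide variants.
    """
    freqs = rng.uniform(maf_range[0], maf_range[1], n_sites)
    h1 = rng.random((n_samples, n_sites)) < freqs
    h2 = rng.random((n_samples, n_sites)) < freqs
    return (h1.astype(np.int8) + h2.astype(np.int8))


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """End-to-end generation with a single seed; bit-reproducible.

    The GRM is computed from a separate set of ``n_grm_sites`` unlinked
    genome-wide markers, not from the cis-region SNPs: a relatedness
    matrix estimated from the very SNPs being tested is rank-deficient
    and lets the polygenic term absorb the association signal.
    """
    from .kinship import compute_grm

    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    trios = simulate_trios(panel, config, rng)
    cov = simulate_covariates(config.n_trios, rng)
    grm_geno = simulate_unlinked_genotypes(
        config.n_trios, config.n_grm_sites, config.maf_range, rng)
    grm = compute_grm(grm_geno)
    tpm, meta = simulate_expression(
        trios.truth.child_pat, trios.truth.child_mat, cov, grm, config, rng,
        snp_table=trios.snp_table(),
    )
    trios.truth.effects = meta[["true_kind", "true_beta1", "true_beta0",
                                "causal_site", "latent_sd"]]
    trios.truth.latent_sd = meta["latent_sd"].to_numpy()
    return SyntheticStudy(config, panel, trios, cov, grm, tpm, meta)
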