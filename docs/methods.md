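# Methods

## Model and estimands

For one gene's prepared expression vector y over n children, the mixed
model is

    y = W a + x beta + u + e,
    u ~ MVN(0, eta / tau * K),    e ~ MVN(0, 1 / tau * I),

where W holds an intercept and mean-centered covariates (age, sex, BMI,
four white-cell fractions), K is the genetic relatedness matrix (twice
the kinship matrix), eta the ratio of polygenic to residual variance and
tau the residual precision. The tested predictor x is one of: the
genotype dosage x1 + x0, the paternal allele x1, the maternal allele x0
(each one degree of freedom), or the pair (x1, x0) jointly (two degrees
of freedom). Genotype dosages are centered; haplotype predictors are the
raw 0/1 alleles, centered. With the flat covariate prior, all Bayes
factors are invariant to centering and to rescaling of y.

### Variance ratio

eta is estimated by maximum likelihood under the covariates-only model,
profiling a and tau analytically and maximizing the 1-D profile
likelihood over eta on a log grid followed by Brent refinement, reusing a
single eigendecomposition of K across all genes. Two degeneracies are
handled explicitly: when the profile is flat (K proportional to I), eta
is unidentifiable and 0 is returned with a warning; when K is singular
and its null space overlaps the covariate span, the likelihood diverges
as eta -> infinity, so boundary "optima" are rejected in favor of the
best interior local maximum (the boundary is only accepted, with a
warning, when the profile increases monotonically). An option exists to
refit eta per SNP with the genotype dosage included among the
covariates; the default fits once per gene, since the refit changes
Bayes factors negligibly at cis-eQTL effect sizes while multiplying the
cost by the number of cis SNPs.

### Closed-form Bayes factors

Priors: a ~ N(0, Va/tau * I), beta_i ~ N(0, sigma^2/tau) iid,
tau ~ Gamma(kappa1/2, kappa2/2), in the limits Va -> infinity,
kappa -> 0. sigma defaults to 0.5. Writing H = eta*K + I and whitening
all vectors by H^(-1/2) (via the shared eigendecomposition), let r be the
whitened y residualized on the whitened W, G~ the whitened, residualized
predictor block (p columns), and

    Omega = G~'G~ + I_p / sigma^2,
    bhat  = Omega^{-1} G~'r,
    Q0    = r'r,     Q1 = Q0 - r'G~ bhat.

Then

    log10 BF = -1/2 log10 |I_p + sigma^2 G~'G~| - (n/2) log10(Q1 / Q0).

The exponent is n/2 (not (n - c)/2): the covariate prior's normalization
is tau-dependent and contributes tau^{c/2} to the marginal. The posterior
of beta is multivariate-t with df n, location bhat and scale
(Q1/n) Omega^{-1}; its covariance Q1/(n-2) Omega^{-1} supplies
(s1^2, s0^2, s12) for the difference test

    t = (bhat1 - bhat0)^2 / (s1^2 + s0^2 - 2 s12),   p = P(chi2_1 > t),

computed from the survival function so that p-values remain accurate
deep in the tail (the per-pair output stores -log10 p via the log
survival function). Correctness of the closed form is arbitrated by an
independent oracle that evaluates the marginal likelihood as a
multivariate-normal density with large-but-finite Va and integrates tau
numerically on a dense log grid; the two agree to < 1e-6 log10 units,
and posterior moments agree with 2-D grid integration. Because the
posterior carries the sigma = 0.5 shrinkage prior, the chi-square null
of the difference test is asymptotic in n: at n = 250 the empirical
5% rejection rate is ~0.037 (conservative); at the study scale of
~10^3 trios it is within sampling error of 0.05.

A log10 BF converts to a posterior probability of association as
PPA = 1 / (1 + 10^{-lgBF} / prior_odds), computed in the overflow-safe
form.

## Phasing

Mendelian rules first: a homozygous child phases itself; a heterozygous
child with at least one homozygous parent is forced; triple-heterozygous
sites are masked. At a Mendelian incompatibility the child's genotype is
trusted — a heterozygous child is masked (indistinguishable from an
unresolvable site), a homozygous child is phased from its own genotype.

Masked sites are imputed under a Li–Stephens copying HMM: states are
reference haplotypes, the template switches with probability rho per
adjacent-site interval (uniformly over the panel, including the current
template), alleles copy with error eps. The posterior alt dosage at a
masked site is sum_h gamma(h) P(alt | template h), with P = 1-eps / eps /
0.5 for template allele 1 / 0 / missing. At each jointly-masked site the
haplotype with the larger dosage receives the alt allele (ties broken by
a seeded coin flip; sites with exactly one missing haplotype are
thresholded at 0.5). Defaults: rho = 0.005, eps = 0.001.

The reference panel is self-contained: the parents' own haplotypes,
phased through their children (transmitted = child haplotype,
untransmitted = genotype minus transmitted allele, missing where
unknown), subsampled to max_panel = 200 haplotypes, with each child's
own parents excluded from its copying prior via a per-query state mask.
Panel entries missing at triple-het sites emit both alleles equally, so
no phase information leaks from a child's own family. Processing is per
chromosome; forward–backward runs batched over children with per-step
normalization.

## Expression preparation

Genes with a zero-TPM fraction of 5% or more (strict inequality for
retention) or without GC content are removed. GC bias is corrected per
sample across genes: fit a local quadratic regression (tricube weights,
span 0.75, neighbourhood floor(span*n) points) of y = log(1+TPM) on GC,
and return median(y) + residuals. The smoother reproduces the standard
loess implementation (degree 2, direct surface) to ~1e-12 on shared
fixtures; above 1500 genes it fits at ~200 quantile knots and
interpolates. Each gene is then replaced by normal scores of its ranks
across samples, with plotting positions (r - 3/8)/(n + 1/4) for n <= 10
and (r - 1/2)/n otherwise, ties receiving average ranks. The composite
map is idempotent and makes every gene's margin standard normal, so
downstream effect sizes are in units of the latent expression SD.

## Classification and enrichment

Cis pairs are all (gene, SNP) with |pos - TSS| <= 1 Mb (closed interval,
1-based positions, strand ignored) on the same chromosome; SNPs need
sample genotype MAF >= 0.01, and each single-allele BF additionally
requires that parental vector to be polymorphic (low parental allele
frequencies are otherwise penalized intrinsically by the BF). Labels use
strict inequalities at lgBF = 4 and theta = log10 2 (0 and log10 3
supported); a record exactly at theta gets no label; for theta <= 4 the
four label rules are mutually exclusive (verified exhaustively).
Sentinels maximize lgBFj with ties broken by distance to TSS, then SNP
id. Gene sets GP/GM/GA/GG collect genes with at least one eQTL of each
class; G1/G0/G2 are the set differences holding exclusively paternal /
maternal / opposing eGenes.

The one-sample proportion test uses the normal approximation with a
continuity correction that shrinks |k/n - f0| toward zero by 1/(2n),
floored at zero — the convention of standard statistical software, which
reproduces the published drug-target p-values on both sides of f0 (a
one-directional correction does not). The two-sample test is the
pooled-variance z-test. Target-set significance is Bonferroni-corrected
over the 12 catalog-by-set tests. Pleiotropy sets Pk (SNPs that are
genotype-eQTL of at least k genes) are nested by construction; all
annotation fractions are computed over distinct SNPs.

## Trio discovery

Per-chromosome kinship (half the centered-and-scaled genotype GRM) is
summarized by its mean and SD across chromosomes. A parent–offspring
pair shares exactly one haplotype IBD on every chromosome, so its
kinship is constant; full sibs match the mean 0.25 but fluctuate from
chromosome to chromosome. (A, B, C) is reported as a trio when
phi(A,B) < 0.1, both |phi(.,C) - 0.25| < 0.1, and both candidate PO
pairs have per-chromosome SD < 0.06; children matching multiple parent
pairs are flagged ambiguous and skipped. The cutoffs were calibrated on
simulated cohorts (22 chromosomes, parent/child/sib truth recorded)
where parent–offspring SDs stay below 0.05 and sib SDs above 0.07; they
are exposed as parameters since the working point depends on marker
density and LD.

## Synthetic data

The generator emulates the study conditions the analysis assumes:

- **Haplotypes.** A seed set (default 12) related by a copy-and-mutate
  genealogy (each seed copies a random earlier one, flipping alleles
  with probability 0.3) supplies locally similar templates; panel and
  parental haplotypes are Markov copying mosaics over them with switch
  probability 0.003 per adjacent-site interval (sites 1 kb apart, so
  block scale ~300 kb). Per-site minor allele frequencies are enforced
  within maf_range (default 0.05–0.5) by redrawing seed columns along
  the fixed genealogy; an unsatisfiable range fails explicitly.
- **Transmission.** Children inherit one recombinant gamete per parent
  at the meiotic rate 1.3e-5 per kb (~1.3 cM/Mb). Population LD scale
  and meiotic recombination are deliberately separate parameters: the
  child's haplotype is a near-exact copy of one parental haplotype,
  while unrelated haplotypes decorrelate at the population scale — the
  regime that makes mask-and-impute phasing accurate in real cohorts.
- **Genotype errors** are injected into parents only (the child is
  treated as correctly genotyped), at 4.76 per 100,000 SNPs per trio, and
  are placed so as to create a Mendelian incompatibility — the
  configured rate is the *observable* Mendelian-error rate; sites where
  no single-parent corruption is detectable (both parents heterozygous)
  are resampled.
- **Expression.** Latent y = Wa + x1 beta1 + x0 beta0 + u + e with
  u ~ MVN(0, eta/tau K), e ~ MVN(0, 1/tau I); defaults eta = 0.5,
  tau = 1 (the residual scale is not identified by rank-normalized
  data, so tau is a free parameter). Emitted TPM = exp(y + gc_bias(GC))
  with an optional zero-inflation probability; since the pipeline uses
  only ranks of log(1+TPM), any monotone emission is equivalent. Effect
  sizes are in units of the residual SD; per-gene truth (class, beta1,
  beta0, causal site, realized latent SD) is recorded.
- **Relatedness.** The GRM comes from a separate block of 2,000 unlinked
  genome-wide markers with unrelated founders, giving a near-identity
  K with O(1/sqrt(M)) noise — the regime of a GRM estimated from
  millions of genome-wide variants. A GRM computed from the cis-region
  SNPs themselves would be rank-deficient, with the genotype space as
  its top eigenspace, and the polygenic term would absorb the
  association signal.
- **Covariates.** Sex ~ Bernoulli(0.5); age, BMI and four cell fractions
  Gaussian with fixed, documented means/SDs; coefficients act on
  standardized covariates.

What the generator does *not* emulate: read-level counts and their
mean–variance structure, sex chromosomes, population stratification,
batch effects (a batch column can be passed as a covariate but no batch
structure is simulated), reference-panel mismatch, and genotyping error
in children. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under the stated model, not robustness to
real-data artifacts outside it.

## Evaluation experiments and problem sizes

`poeqtl.evaluation` runs the pipeline against recorded truth at sizes
chosen to mirror the study regime while remaining desk-scale:

- Phasing accuracy: 200 trios x 5,000 sites (~84,000 triple-het sites);
  error ~0.8 per 1,000 at defaults, well under the 1-in-200 bound.
- Difference-test calibration: 2,000 genes at n = 1,000 trios.
- Planted-effect recovery: 1,000 trios, 12 genes per effect class with
  |beta| in [0.75, 1.5] residual SD and causal MAF >= 0.1, plus 132 null
  genes. The null block keeps the per-sample GC smoother's per-gene
  leverage realistically small; with only a few dozen genes the smoother
  absorbs part of each gene's own signal (a real transcriptome has
  ~17,000 genes). Credible-interval coverage is assessed against the
  standardized truth beta / sd(latent y), which is the estimand after
  rank-normalization; the modal assigned label per class and per-class
  accuracies are reported alongside. Note that posterior means under the
  sigma = 0.5 shrinkage prior are pulled toward zero by a fraction of a
  posterior SD when the true standardized effect sits in the prior's
  tail (as the planted 0.75-1.5 SD effects do), so the empirical 95%
  coverage hovers around 0.90 rather than exactly 0.95 — the expected
  behavior of credible intervals evaluated at fixed large truths, not an
  implementation defect.

## Numerical choices

- Forward–backward uses per-step normalization (no log-space needed);
  posteriors overwrite the forward buffer to halve peak memory; children
  are processed in chunks of 32.
- Whitening rotations U'X are computed once per dataset and rescaled per
  gene by (eta lambda + 1)^{-1/2}; per-gene scans vectorize all four BFs
  across SNPs with explicit 2x2 algebra, verified to machine precision
  against the scalar path.
- GRM eigenvalues are clipped at zero within tolerance; matrices with
  genuinely negative eigenvalues are rejected.
- Dosage ties (exactly 0.5) are broken by a seeded coin flip: measure
  zero in theory, but determinism under a fixed seed is part of the
  pipeline contract (outputs are byte-identical across reruns).
- The VCF/PED/TSV/GRM writers emit exactly the formats the readers
  parse, so synthetic studies round-trip through disk like real inputs.

## Known limitations

- The eta MLE is a grid-plus-Brent optimizer; likelihoods with multiple
  interior optima beyond the grid resolution (40 points over
  [1e-3, 1e4]) could in principle be missed.
- The difference test's chi-square null is asymptotic; at n below a few
  hundred it is conservative (see above).
- Trio discovery assumes genotyped parents in the cohort and does not
  model avuncular or grandparent relationships, which real kinship
  tooling distinguishes with additional statistics.
- The self-contained imputation panel requires a few hundred trios to be
  informative; with very few trios the triple-het error rate rises.
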