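# poeqtl

Parent-of-origin-effect (POE) eQTL mapping from family trios.

Most cis-eQTL studies test the *count* of an allele against a gene's
expression. That test is blind to effects that depend on which parent the
allele came from: genomic imprinting silences one parental copy, so a
variant can act only through its paternal (or only its maternal) allele,
and paternal and maternal effects can even point in opposite directions —
in which case the genotype test sees nothing at all. `poeqtl` implements a
trio-based analysis that separates the two parental alleles and tests them
jointly:

1. **Trio phasing.** Each child is phased into a paternal and a maternal
   haplotype by Mendelian rules; triple-heterozygous sites (father, mother
   and child all heterozygous) are masked, imputed on each haplotype
   background with a Li–Stephens copying HMM, and resolved by comparing
   the two imputed dosages (the larger dosage takes the alt allele).
2. **Expression preparation.** Genes with ≥ 5% zero TPM values are
   dropped; GC-content bias is regressed out of log(1+TPM) per sample with
   a local quadratic (loess) smoother; each gene is then rank-normalized
   to normal scores across samples.
3. **Association.** For expression *y* with covariates *W* (age, sex,
   BMI, cell composition) under the linear mixed model

   y = Wa + x&beta; + u + e,&emsp;u ~ N(0, &tau;<sup>-1</sup>&eta;K),&emsp;e ~ N(0, &tau;<sup>-1</sup>I),

   with K the genetic relatedness matrix (twice kinship) and &eta; fitted
   by maximum likelihood once per gene, four log<sub>10</sub> Bayes
   factors are computed in closed form against the covariates-only null
   under conjugate priors (a ~ N(0, &tau;<sup>-1</sup>V<sub>a</sub>),
   &beta; ~ N(0, &tau;<sup>-1</sup>&sigma;&sup2;), &tau; ~ &Gamma;, in the
   V<sub>a</sub> → ∞, &kappa; → 0 limits; &sigma; = 0.5): **BFg** for the
   genotype x<sub>1</sub>+x<sub>0</sub>, **BF1** for the paternal allele,
   **BF0** for the maternal allele, and **BFj** for the joint pair. The
   joint model also yields posterior effects
   (&beta;&#x302;<sub>1</sub>, &beta;&#x302;<sub>0</sub>) and the
   difference statistic
   t = (&beta;&#x302;<sub>1</sub> − &beta;&#x302;<sub>0</sub>)² /
   (s₁² + s₀² − 2s₁₀), &chi;²₁ under the null.
4. **Classification** (threshold log₁₀BF = 4, secondary threshold
   &theta; = log₁₀2): paternal eQTL **SP** (BF1 > 4, BF0 < &theta;),
   maternal **SM** (mirror), opposing **SO** (BFj − BFg > 4, both parental
   BFs > &theta;, effects of opposite sign) and genotype **SG** (BFg > 4,
   both > &theta;, same sign), plus sentinel eQTL (largest BFj per gene)
   and exclusive gene sets G1/G0/G2.
5. **Enrichment.** Proportion tests (continuity-corrected one-sample,
   pooled two-sample) and pleiotropy/annotation summaries over eQTL and
   eGene sets against externally supplied annotation and drug-target
   catalogs.

Real trio cohorts with RNAseq are access-controlled, so the package ships
a synthetic-data generator (`poeqtl.simulate`) that reproduces the
statistical structure the analysis assumes — LD-structured haplotypes,
Mendelian transmission with recombination, rare parental genotype errors,
planted effects of every class, a polygenic term, GC bias — with full
recorded truth, making every stage testable offline.

## Worked example

```python
import numpy as np
from poeqtl import EigenGRM, bf_joint, ppa

rng = np.random.default_rng(3)
n = 800
x1 = rng.integers(0, 2, n).astype(float)   # paternal allele
x0 = rng.integers(0, 2, n).astype(float)   # maternal allele
W = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
y = 1.0 * x1 + rng.normal(size=n)          # paternal-only effect

stats = bf_joint(y, W, x1, x0, EigenGRM(np.eye(n)), eta=0.0)
```

Running this (examples/03_bayes_factors.py) prints

```
lgBFg (genotype test, 1 df):   15.3
lgBF1 (paternal allele):       31.4
lgBF0 (maternal allele):       -0.8
lgBFj (joint, 2 df):           30.6
posterior effects: beta1 = 0.93 (truth 1.0), beta0 = 0.02 (truth 0.0)
difference test: t = 77.8, p = 1.15e-18
PPA of the paternal signal at 1:1000 prior odds: 1.0000
```

The genotype test halves the signal by averaging the silent maternal
allele into the predictor (lgBFg 15.3 vs lgBF1 31.4); the maternal BF is
null; the difference test rejects &beta;₁ = &beta;₀ decisively — the
signature of a paternal eQTL (label SP). A log₁₀BF of 4 converts to a
posterior probability of association of 0.91 at 1:1000 prior odds
(`ppa(4, 1/1000)`).

The `examples/` directory has one short script per capability
(simulation, phasing accuracy, Bayes factors, classification +
enrichment, full pipeline); each prints the numbers it computes and what
they mean. A thin CLI wraps the pipeline:

```bash
poeqtl simulate --n-trios 300 --n-sites 2000 --n-genes 50 --seed 1 --out study/
poeqtl run-all --config study/pipeline_config.yaml
```

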