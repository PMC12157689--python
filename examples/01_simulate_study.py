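"""Generate a synthetic trio eQTL study and write the pipeline's input files.

The generator draws LD-structured founder haplotypes, transmits them
through trios with meiotic recombination and rare parental genotype
errors, and emits TPM-like expression with planted paternal / maternal /
opposing / genotype cis effects plus a polygenic component.
"""

from poeqtl import SimConfig, simulate_study, write_study

cfg = SimConfig(n_trios=120, n_sites=500, n_genes=40, seed=7)
study = simulate_study(cfg)

print(f"trios: {study.trios.n_trios}, sites: {study.trios.n_sites}, "
      f"genes: {len(study.tpm)}")
print("planted effect classes:",
      study.gene_meta["true_kind"].value_counts().to_dict())
print("injected parental genotype errors:",
      len(study.trios.truth.error_sites))

pc = write_study(study, "scratch/example_study")
print(f"input files written; pipeline config points at {pc.vcf} etc.")
# The truth (true phase, effect sizes, class labels) stays in
# study.trios.truth / study.gene_meta for later comparison.
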