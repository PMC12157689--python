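"""Phase children into paternal and maternal haplotypes and measure accuracy.

Mendelian rules resolve every site except triple heterozygotes (father,
mother and child all heterozygous); those are masked, imputed on each
parental haplotype background with a Li-Stephens copying model, and the
haplotype with the larger imputed dosage receives the alt allele.
"""

import numpy as np

from poeqtl import SimConfig, simulate_panel, simulate_trios
from poeqtl.phasing import UNRESOLVED, mendelian_phase, phase_trio_dataset

cfg = SimConfig(n_trios=80, n_sites=2000, seed=17)
rng = np.random.default_rng(cfg.seed)
panel = simulate_panel(cfg, rng)
trios = simulate_trios(panel, cfg, rng)

phased = phase_trio_dataset(trios.g_father, trios.g_mother, trios.g_child,
                            seed=1)

errs = tot = 0
for i, p in enumerate(phased):
    m = mendelian_phase(trios.g_father[i], trios.g_mother[i],
                        trios.g_child[i])
    triple = m.resolved_by == UNRESOLVED
    tot += int(triple.sum())
    errs += int((p.h_pat[triple] != trios.truth.child_pat[i][triple]).sum())

print(f"triple-heterozygous sites: {tot} "
      f"({tot / (cfg.n_trios * cfg.n_sites):.1%} of all genotypes)")
print(f"phasing errors at those sites: {errs} "
      f"(rate {errs / tot:.2%}, i.e. {200 * errs / tot:.2f} per 200)")
# An error rate below 1/200 = 0.5% means the parental origin of almost
# every allele is assigned correctly, which is what the four-way
# association test downstream relies on.
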