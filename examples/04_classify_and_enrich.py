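"""Classify published sentinel eQTL statistics and test target enrichment.

The bundled table holds ten sentinel eQTL from a family-based whole-blood
study; the classification rule (theta = log10 2) sorts them into
paternal (SP), maternal (SM), opposing (SO) and genotype (SG) classes.
The bundled drug-target counts feed one-sided proportion tests with a
continuity correction.
"""

from poeqtl.classify import classify_records
from poeqtl.datasets import example_sentinels, example_target_counts
from poeqtl.enrichment import prop_test_one_sample

sent = classify_records(example_sentinels())
print(sent[["gene_id", "lgBFg", "lgBF1", "lgBF0", "lgBFj", "label"]]
      .to_string(index=False))
# NDN-like rows (huge lgBF1, null lgBF0) are paternal; MEG3-like rows
# maternal; NECAB3/LSM7 have opposite-signed effects detected only by
# the joint test (SO); ZNF890P/PPIEL carry concordant effects (SG).

print("\ndrug-target enrichment (one-sided test of proportion):")
for _, r in example_target_counts().iterrows():
    f_hat, p = prop_test_one_sample(int(r["n_target"]), int(r["n_gene"]),
                                    float(r["f0"]), side="greater")
    flag = " *" if p < 0.05 / 12 else ""
    print(f"  {r['catalog']:>14} {r['set']}: f_hat={f_hat:.4f} "
          f"vs f0={r['f0']:.4f}, p={p:.2g}{flag}")
print("  (* significant after Bonferroni correction over 12 tests)")
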