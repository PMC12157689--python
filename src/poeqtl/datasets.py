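"""Small bundled example tables.

Published summary statistics from a large family-based whole-blood
parent-of-origin eQTL study, bundled as worked-example inputs: the ten
sentinel eQTL with the most significant paternal-vs-maternal difference,
and the drug-target enrichment counts of its four eGene sets. They let
the classification rules and the proportion-test machinery run on real
printed numbers without any external download.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["example_sentinels", "example_target_counts", "example_gwas_counts"]

_SENTINELS_TSV = """\
gene_id\ttss_mb\tsnp_id\tlgBFg\tlgBF1\tlgBF0\tlgBFj\tbeta1\tbeta0\tneglog10_p_diff
MEG3\t100.78\trs12881545\t35.7\t-0.7\t86.3\t85.7\t1.0\t-21.2\t54.0
PPIEL\t39.53\trs79473113\t47.6\t84.6\t0.5\t85.8\t-20.5\t-2.7\t38.3
NDN\t23.69\trs3743340\t36.5\t68.5\t-0.2\t67.7\t18.6\t0.8\t33.2
PEG10\t94.66\trs7801134\t2.6\t13.3\t-0.1\t13.6\t-8.2\t2.4\t12.6
ZNF331\t53.52\trs1284523\t6.3\t-0.9\t15.9\t14.9\t-0.5\t8.8\t10.3
ZNF890P\t5.12\trs112844843\t125.8\t94.7\t31.1\t133.9\t23.2\t13.6\t10.1
FAM50B\t3.85\trs111515624\t3.5\t11.5\t-0.5\t10.9\t-7.4\t0.6\t8.6
NECAB3\t33.66\trs2626556\t-0.7\t1.2\t4.6\t5.5\t-2.9\t4.9\t7.8
SNURF\t24.95\trs4906936\t5.1\t12.1\t-0.9\t11.2\t7.7\t-0.1\t7.6
LSM7\t2.32\trs393651\t-1.0\t3.5\t1.6\t4.9\t4.4\t-3.3\t7.5
"""

# Drug-target enrichment counts per eGene set: set size n, target count k,
# and the genome-wide background target rate f0, for three catalogs.
_TARGETS_TSV = """\
catalog\tset\tn_gene\tn_target\tf0
successful\tGA\t180\t7\t0.0220
successful\tGP\t1188\t38\t0.0220
successful\tGM\t1209\t23\t0.0220
successful\tGG\t4940\t124\t0.0220
clinical_trial\tGA\t180\t7\t0.0421
clinical_trial\tGP\t1188\t69\t0.0421
clinical_trial\tGM\t1209\t67\t0.0421
clinical_trial\tGG\t4940\t254\t0.0421
combined\tGA\t180\t14\t0.0641
combined\tGP\t1188\t107\t0.0641
combined\tGM\t1209\t90\t0.0641
combined\tGG\t4940\t374\t0.0641
"""

# Distinct-SNP counts and GWAS-hit fractions per eQTL class
_GWAS_TSV = """\
set\tn_snp\tgwas_frac
SO\t485\t0.023
SP\t14372\t0.066
SM\t13293\t0.050
SG\t577701\t0.054
"""


def example_sentinels() -> pd.DataFrame:
    """Ten example sentinel eQTL with their four Bayes factors and joint
    effect estimates (TSS in Mb, HG38)."""
    return pd.read_csv(io.StringIO(_SENTINELS_TSV), sep="\t")


def example_target_counts() -> pd.DataFrame:
    """Drug-target counts per eGene set for three target catalogs."""
    return pd.read_csv(io.StringIO(_TARGETS_TSV), sep="\t")


def example_gwas_counts() -> pd.DataFrame:
    """Distinct-SNP counts and GWAS-hit fractions per eQTL class."""
    return pd.read_csv(io.StringIO(_GWAS_TSV), sep="\t")
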