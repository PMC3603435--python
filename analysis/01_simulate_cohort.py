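#!/usr/bin/env python
"""Generate the synthetic study cohort.

Builds a four-stratum cohort (535 African-ancestry men, 568 African-ancestry
women, 1131 European-ancestry men, 1393 European-ancestry women) with the
per-stratum substance-dependence prevalences and age distributions the
pipeline is designed for, 100 SNPs in 5-SNP LD blocks, and a rare opiates
risk variant (MAF 1.6%, per-allele OR 13.87) planted in the first block.
Writes PLINK-text genotypes, the phenotype TSV and a gene annotation under
scratch/data/.
"""

import numpy as np

from gwastrat.datatypes import TRAITS
from gwastrat.io import write_gene_table, write_plink_text
from gwastrat.simulate import RiskSNP, SimConfig, gen_cohort, gen_gene_annotation

PREFIX = "scratch/data/cohort"
SEED = 2026


def main() -> None:
    beta = np.zeros(len(TRAITS))
    beta[TRAITS.index("opiates")] = np.log(13.87)
    cfg = SimConfig(
        n_snps=100, ld_block_size=5, ld_rho=0.8, maf_range=(0.05, 0.5),
        seed=SEED, risk_snp=RiskSNP(2, beta, maf=0.016), missing_rate=0.01,
    )
    G, S, _pool = gen_cohort(cfg)
    paths = write_plink_text(G, S, PREFIX)
    write_gene_table(gen_gene_annotation(cfg), f"{PREFIX}.genes.tsv")
    print(f"cohort: {G.n_samples} samples x {G.n_snps} SNPs, "
          f"risk SNP snp00002 (MAF 0.016, OR 13.87 on opiates)")
    for p in paths:
        print("wrote", p)
    print("wrote", f"{PREFIX}.genes.tsv")


if __name__ == "__main__":
    main()
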