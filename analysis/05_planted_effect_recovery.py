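#!/usr/bin/env python
"""Recovery of the planted rare risk variant at the reference cohort scale.

200 replicates of a 535-subject stratum with a MAF-1.6% variant carrying a
per-allele odds ratio of 13.87 on the opiates trait; measures the mean
logistic-slope estimate of the log odds ratio, the mean allelic log-OR, and
how often the gene holding the variant attains the genome-wide smallest
gene-level P.  Writes results/planted_recovery.tsv.
"""

import numpy as np
import pandas as pd

from gwastrat.studies import recovery_study

SEED = 2026


def main() -> None:
    out = recovery_study(n_reps=200, seed=SEED)
    df = pd.DataFrame(
        [
            ("mean_logistic_log_or", out["mean_logistic_log_or"]),
            ("mc_se_logistic_log_or", out["se_logistic_log_or"]),
            ("mean_allelic_log_or", out["mean_allelic_log_or"]),
            ("target_log_or", out["target_log_or"]),
            ("gene_ranked_first_rate", out["gene_ranked_first_rate"]),
            ("n_usable_replicates", out["n_reps"]),
        ],
        columns=["quantity", "value"],
    )
    df.to_csv("results/planted_recovery.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    gap = out["mean_logistic_log_or"] - out["target_log_or"]
    print(f"\nlogistic slope recovers log(13.87)={out['target_log_or']:.4f} "
          f"(gap {gap:+.4f}, {abs(gap)/out['se_logistic_log_or']:.1f} MC SE); "
          f"the allelic log-OR ({out['mean_allelic_log_or']:.3f}) is mildly "
          "attenuated, as expected when cases are strongly enriched for a "
          "rare allele; the planted gene ranks first in "
          f"{100*out['gene_ranked_first_rate']:.0f}% of replicates.")


if __name__ == "__main__":
    main()
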