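#!/usr/bin/env python
"""Reproduce the rare-variant contingency analysis on the exact fixture.

The fixture places the case/control genotype counts 35/9/0 and 483/8/0 of
a rare variant (rs2377339-like) in 535 subjects and recomputes every
summary: allele table, odds ratio, allelic chi-square P, pooled MAF,
carrier proportions, and the logistic Wald P.  Writes
results/contingency_anchors.tsv.
"""

import pandas as pd

from gwastrat.studies import table3_anchor_summary


def main() -> None:
    s = table3_anchor_summary()
    a, b, c, d = s["allele_table"]
    rows = [
        ("case_minor_alleles", a),
        ("case_major_alleles", b),
        ("control_minor_alleles", c),
        ("control_major_alleles", d),
        ("odds_ratio", round(s["odds_ratio"], 4)),
        ("allelic_chi2", round(s["allelic_chi2"], 4)),
        ("allelic_p", s["allelic_p"]),
        ("logistic_p", s["logistic_p"]),
        ("pooled_maf_percent", round(s["maf_percent"], 4)),
        ("case_carrier_percent", round(s["case_carrier_percent"], 4)),
        ("control_carrier_percent", round(s["control_carrier_percent"], 4)),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    df.to_csv("results/contingency_anchors.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print("\nallelic OR 13.87 with P ~ 1.3e-11: the allelic test treats the"
          " 17 minor alleles as 17 Bernoulli draws; the logistic Wald P"
          " (~1.1e-7) is weaker because the Wald SE is inflated for a slope"
          " this far from zero with so few carriers.")


if __name__ == "__main__":
    main()
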