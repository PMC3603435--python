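"""Quality control and stratification.

Default thresholds follow the usual GWAS QC recipe for this study design:
samples with genotype call rate < 90% are excluded, SNPs with minor allele
frequency < 1% are excluded, and SNPs failing the Hardy-Weinberg exact test
at P <= 1e-4 are excluded.  Boundary semantics are literal: a call rate of
exactly 90% or a MAF of exactly 1% is retained, an HWE P of exactly 1e-4 is
removed.  The HWE test is the exact conditional test (enumeration over
heterozygote counts), not the chi-square approximation — at MAF ~1.6% the
chi-square is unreliable.

Analyses are stratified into the four ancestry x sex subsamples to avoid
population-structure confounding; all filters can be applied per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import STRATA, DataError, GenotypeMatrix, validate_sample_table


@dataclass
class QCReport:
    """Bookkeeping for one QC step (or an accumulated sequence of steps)."""

    n_samples_in: int = 0
    n_snps_in: int = 0
    n_samples_out: int = 0
    n_snps_out: int = 0
    n_samples_removed_callrate: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_hwe: int = 0
    per_stratum_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def check(self) -> None:
        if self.n_samples_in - self.n_samples_removed_callrate != self.n_samples_out:
            raise DataError("QCReport sample counts inconsistent")
        removed_snps = self.n_snps_removed_maf + self.n_snps_removed_hwe
        if self.n_snps_in - removed_snps != self.n_snps_out:
            raise DataError("QCReport SNP counts inconsistent")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_removed_callrate", self.n_samples_removed_callrate),
            ("samples_out", self.n_samples_out),
            ("snps_in", self.n_snps_in),
            ("snps_removed_maf", self.n_snps_removed_maf),
            ("snps_removed_hwe", self.n_snps_removed_hwe),
            ("snps_out", self.n_snps_out),
        ]
        rows += [(f"stratum_{k}_n", v) for k, v in self.per_stratum_counts.items()]
        return pd.DataFrame(rows, columns=["quantity", "count"])


def sample_call_rate_filter(
    G: GenotypeMatrix, min_rate: float = 0.90
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples whose genotype call rate is strictly below ``min_rate``."""
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    if G.n_samples == 0:
        raise DataError("empty genotype matrix")
    keep = G.sample_call_rate() >= min_rate
    out = G.take_samples(keep)
    rep = QCReport(
        n_samples_in=G.n_samples,
        n_snps_in=G.n_snps,
        n_samples_out=out.n_samples,
        n_snps_out=out.n_snps,
        n_samples_removed_callrate=int((~keep).sum()),
    )
    rep.check()
    return out, rep


def snp_maf_filter(
    G: GenotypeMatrix, min_maf: float = 0.01
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with minor allele frequency strictly below ``min_maf``."""
    if not 0 < min_maf < 0.5:
        raise ValueError("min_maf must be in (0, 0.5)")
    keep = G.maf() >= min_maf
    out = G.take_snps(keep)
    rep = QCReport(
        n_samples_in=G.n_samples,
        n_snps_in=G.n_snps,
        n_samples_out=out.n_samples,
        n_snps_out=out.n_snps,
        n_snps_removed_maf=int((~keep).sum()),
    )
    if out.n_snps == 0:
        rep.warnings.append("all SNPs removed by MAF filter")
    rep.check()
    return out, rep


def hwe_exact_pvalue(nAA: int, nAa: int, naa: int) -> float:
    """Two-sided Hardy-Weinberg exact test P value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose point probability does not exceed that of
    the observed table.  Probabilities follow the conditional distribution

        P(n_Aa | n, n_A)  ∝  n! / (n_AA! n_Aa! n_aa!) * 2^{n_Aa},

    evaluated in log space for numerical range.
    """
    nAA, nAa, naa = int(nAA), int(nAa), int(naa)
    if min(nAA, nAa, naa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = nAA + nAa + naa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_minor = min(2 * nAA + nAa, 2 * naa + nAa)
    # heterozygote count shares the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_hom_rare = (n_minor - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(n_hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[hets == nAa]
    if observed.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    # small relative slack so ties (incl. the observed table) are included
    p = prob[prob <= observed[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_filter(
    G: GenotypeMatrix, threshold: float = 0.0001
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs whose HWE exact P value is not strictly above ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    counts = G.genotype_counts()
    pvals = np.array([hwe_exact_pvalue(c[0], c[1], c[2]) for c in counts])
    keep = pvals > threshold
    out = G.take_snps(keep)
    rep = QCReport(
        n_samples_in=G.n_samples,
        n_snps_in=G.n_snps,
        n_samples_out=out.n_samples,
        n_snps_out=out.n_snps,
        n_snps_removed_hwe=int((~keep).sum()),
    )
    rep.check()
    return out, rep


def orient_minor_allele(G: GenotypeMatrix) -> GenotypeMatrix:
    """Re-orient A1 to the minor allele (dosage counts minor copies)."""
    freq = G.allele1_freq()
    flip = np.where(np.isnan(freq), False, freq > 0.5)
    dosage = G.dosage.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    meta = G.snp_meta.copy()
    a1 = meta["a1"].to_numpy(dtype=object).copy()
    a2 = meta["a2"].to_numpy(dtype=object).copy()
    a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
    meta["a1"], meta["a2"] = a1, a2
    return GenotypeMatrix(dosage, meta, G.sample_ids.copy())


def stratify(
    G: GenotypeMatrix, S: pd.DataFrame
) -> dict[tuple[str, str], tuple[GenotypeMatrix, pd.DataFrame]]:
    """Split into the four ancestry x sex strata.

    Returns a dict keyed by ``(ancestry, sex)`` covering all four strata
    (possibly with zero samples).  The strata partition the input: ids are
    pairwise disjoint and their union is the input id set.
    """
    S = validate_sample_table(S)
    ids_g = set(G.sample_ids)
    ids_s = set(S["sample_id"])
    if not ids_g <= ids_s:
        raise DataError(f"samples missing from phenotype table: {sorted(ids_g - ids_s)[:5]}")
    # align phenotype rows to genotype row order
    S = S.set_index("sample_id").loc[list(G.sample_ids)].reset_index()
    out = {}
    for ancestry, sex in STRATA:
        mask = ((S["ancestry"] == ancestry) & (S["sex"] == sex)).to_numpy()
        out[(ancestry, sex)] = (
            G.take_samples(mask),
            S.loc[mask].reset_index(drop=True),
        )
    return out


def default_qc(
    G: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.01,
    hwe_threshold: float = 0.0001,
) -> tuple[GenotypeMatrix, QCReport]:
    """Call-rate -> MAF -> HWE filter sequence with a combined report."""
    g1, r1 = sample_call_rate_filter(G, min_call_rate)
    g2, r2 = snp_maf_filter(g1, min_maf)
    g3, r3 = hwe_filter(g2, hwe_threshold)
    rep = QCReport(
        n_samples_in=G.n_samples,
        n_snps_in=G.n_snps,
        n_samples_out=g3.n_samples,
        n_snps_out=g3.n_snps,
        n_samples_removed_callrate=r1.n_samples_removed_callrate,
        n_snps_removed_maf=r2.n_snps_removed_maf,
        n_snps_removed_hwe=r3.n_snps_removed_hwe,
        warnings=r1.warnings + r2.warnings + r3.warnings,
    )
    rep.check()
    return g3, rep
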