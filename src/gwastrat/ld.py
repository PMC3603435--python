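"""Pairwise linkage disequilibrium from unphased genotypes and SNP-to-gene
mapping.

r² is computed from maximum-likelihood two-locus haplotype frequencies
obtained by EM over the double-heterozygote phase ambiguity — the standard
estimator for unphased case-control data.  Gene assignment uses a
strand-aware asymmetric window (20 kb 5' upstream, 10 kb 3' downstream of
the gene body) with a single LD-extension pass that pulls in SNPs in strong
LD (r² > 0.9) with any initially mapped SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DataError, GenotypeMatrix


@dataclass
class GeneModel:
    """A gene body plus the SNPs assigned to it."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive
    end: int
    mapped_snps: list = field(default_factory=list)
    ld_extended: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError("strand must be '+' or '-'")
        if self.start > self.end:
            raise DataError("gene start must be <= end")


def _pair_complete(g1, g2):
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise DataError("dosage vectors differ in length")
    keep = ~(np.isnan(g1) | np.isnan(g2))
    return g1[keep], g2[keep]


def em_two_locus(g1, g2, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """ML two-locus haplotype frequencies (p_AB, p_Ab, p_aB, p_ab) by EM.

    A is the A1 allele at locus 1, B at locus 2.  Only the double
    heterozygote (1,1) is phase-ambiguous; EM splits its 2n_11 haplotypes
    between AB/ab and Ab/aB in proportion to the current estimate of
    p_AB*p_ab vs p_Ab*p_aB.  Monomorphic input yields the degenerate
    product of marginals in one step.
    """
    g1, g2 = _pair_complete(g1, g2)
    n = g1.size
    if n == 0:
        raise DataError("no pairwise-complete genotypes")
    # 3x3 genotype table: rows dosage at locus 1, cols at locus 2
    tab = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            tab[i, j] = np.sum((g1 == i) & (g2 == j))
    total_haps = 2.0 * n

    # known haplotype contributions (everything except the double het)
    #   locus1 dosage counts copies of A; locus2 of B
    base = np.zeros(4)  # AB, Ab, aB, ab
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            cnt = tab[i, j]
            nA, na = i, 2 - i
            nB, nb = j, 2 - j
            # unambiguous: min(nA, nB) copies of AB etc. — each genotype
            # other than the double het has a unique phase decomposition
            ab_hap = min(na, nb)
            AB_hap = min(nA, nB)
            Ab_hap = nA - AB_hap
            aB_hap = nB - AB_hap
            # consistency: AB+Ab = nA, AB+aB = nB, sum = 2
            base += cnt * np.array([AB_hap, Ab_hap, aB_hap, ab_hap])
    n_dh = tab[1, 1]

    pA = (2 * tab[2, :].sum() + tab[1, :].sum()) / total_haps
    pB = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / total_haps
    if n_dh == 0:
        freq = base / total_haps
        return np.clip(freq, 0.0, 1.0) / max(freq.sum(), 1e-300)

    def run_em(w0: float) -> np.ndarray:
        counts = base + n_dh * np.array([w0, 1 - w0, 1 - w0, w0])
        freq = counts / total_haps
        for _ in range(max_iter):
            coupling = freq[0] * freq[3]
            repulsion = freq[1] * freq[2]
            denom = coupling + repulsion
            w = 0.5 if denom == 0 else coupling / denom
            counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
            new = counts / total_haps
            if np.abs(new - freq).max() < tol:
                return new
            freq = new
        return freq

    # the observed-data likelihood can be bimodal in the double-het split;
    # run EM from coupling-, neutral- and repulsion-leaning starts and keep
    # the highest-likelihood solution
    best, best_ll = None, -np.inf
    for w0 in (0.02, 0.5, 0.98):
        cand = run_em(w0)
        ll = _two_locus_loglik(cand, tab)
        if ll > best_ll:
            best, best_ll = cand, ll
    return best


def _two_locus_loglik(freq: np.ndarray, tab: np.ndarray) -> float:
    """Observed-data multinomial log-likelihood of the 3x3 genotype table."""
    pAB, pAb, paB, pab = np.clip(freq, 1e-300, 1.0)
    probs = np.array(
        [
            [pab**2, 2 * paB * pab, paB**2],
            [2 * pAb * pab, 2 * pAB * pab + 2 * pAb * paB, 2 * pAB * paB],
            [pAb**2, 2 * pAB * pAb, pAB**2],
        ]
    )
    with np.errstate(divide="ignore"):
        logp = np.log(np.clip(probs, 1e-300, None))
    return float((tab * logp).sum())


def r2(g1, g2) -> float:
    """Squared allelic correlation r² from EM haplotype frequencies.

    Returns 0.0 for monomorphic input (no variation, no disequilibrium).
    """
    g1c, g2c = _pair_complete(g1, g2)
    if g1c.size == 0 or np.ptp(g1c) == 0 or np.ptp(g2c) == 0:
        return 0.0
    f = em_two_locus(g1, g2)
    pA = f[0] + f[1]
    pB = f[0] + f[2]
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return 0.0
    D = f[0] - pA * pB
    return float(np.clip(D * D / denom, 0.0, 1.0))


def ld_pair_list(
    G: GenotypeMatrix, threshold: float = 0.2, window_kb: float | None = None
) -> pd.DataFrame:
    """All unordered SNP pairs with r² strictly above ``threshold``.

    With ``window_kb`` set, only same-chromosome pairs within that physical
    distance are evaluated.  Returns a DataFrame (snp_i, snp_j, r2).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    meta = G.snp_meta
    records = []
    for i in range(G.n_snps):
        for j in range(i + 1, G.n_snps):
            if window_kb is not None:
                if meta["chrom"][i] != meta["chrom"][j]:
                    continue
                if abs(int(meta["pos"][i]) - int(meta["pos"][j])) > window_kb * 1000:
                    continue
            val = r2(G.dosage[:, i], G.dosage[:, j])
            if val > threshold:
                records.append((meta["snp_id"][i], meta["snp_id"][j], val))
    return pd.DataFrame(records, columns=["snp_i", "snp_j", "r2"])


def map_snps_to_gene(
    gene: GeneModel,
    snp_meta: pd.DataFrame,
    upstream_kb: float = 20,
    downstream_kb: float = 10,
    strand_aware: bool = True,
) -> GeneModel:
    """Assign SNPs to a gene using the asymmetric upstream/downstream window.

    For a + strand gene the window is [start - upstream, end + downstream];
    for a - strand gene the 5' side is the right (higher-coordinate) side,
    so the window is [start - downstream, end + upstream].  Boundaries are
    inclusive; windows are clipped at position 1.  With
    ``strand_aware=False`` the + strand rule is applied regardless of
    strand.
    """
    up = int(round(upstream_kb * 1000))
    down = int(round(downstream_kb * 1000))
    if gene.strand == "+" or not strand_aware:
        lo, hi = gene.start - up, gene.end + down
    else:
        lo, hi = gene.start - down, gene.end + up
    lo = max(lo, 1)
    sel = (
        (snp_meta["chrom"].astype(str) == str(gene.chrom))
        & (snp_meta["pos"] >= lo)
        & (snp_meta["pos"] <= hi)
    )
    order = snp_meta.loc[sel].sort_values("pos")
    return GeneModel(
        gene.gene_id,
        gene.chrom,
        gene.strand,
        gene.start,
        gene.end,
        mapped_snps=list(order["snp_id"]),
    )


def extend_by_ld(gene: GeneModel, G: GenotypeMatrix, r2_min: float = 0.9) -> GeneModel:
    """One-pass LD extension of a gene's SNP set.

    Adds any same-chromosome SNP with r² strictly above ``r2_min`` to at
    least one *initially* mapped SNP.  Exactly one pass — newly added SNPs
    do not recruit further SNPs, and an already-extended gene is returned
    unchanged — so the operation is idempotent.
    """
    if not gene.mapped_snps or gene.ld_extended:
        return gene
    meta = G.snp_meta
    mapped = set(gene.mapped_snps)
    mapped_idx = [G.snp_index(s) for s in gene.mapped_snps]
    added = []
    for j in range(G.n_snps):
        sid = meta["snp_id"][j]
        if sid in mapped or str(meta["chrom"][j]) != str(gene.chrom):
            continue
        for i in mapped_idx:
            if r2(G.dosage[:, i], G.dosage[:, j]) > r2_min:
                added.append((int(meta["pos"][j]), sid))
                break
    new_snps = list(gene.mapped_snps) + [sid for _, sid in sorted(added)]
    return GeneModel(
        gene.gene_id, gene.chrom, gene.strand, gene.start, gene.end,
        new_snps, ld_extended=True,
    )
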