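"""Two-locus EM, r², LD pair lists and SNP-to-gene mapping."""

import numpy as np
import pytest
from scipy import stats

from gwastrat.ld import (
    GeneModel,
    em_two_locus,
    extend_by_ld,
    ld_pair_list,
    map_snps_to_gene,
    r2,
)

from conftest import make_genotypes


def _genotypes_from_hap_freq(rng, f, n):
    """Draw n unphased genotypes from 4-vector haplotype freqs (AB,Ab,aB,ab)."""
    haps = rng.choice(4, size=(n, 2), p=f)
    g1 = (haps < 2).sum(axis=1).astype(float)  # AB, Ab carry allele A
    g2 = np.isin(haps, (0, 2)).sum(axis=1).astype(float)  # AB, aB carry B
    return g1, g2


def _multinomial_loglik(freqs, g1, g2):
    pAB, pAb, paB, pab = np.clip(freqs, 1e-300, 1.0)
    probs = {
        (2, 2): pAB**2, (2, 1): 2 * pAB * pAb, (2, 0): pAb**2,
        (1, 2): 2 * pAB * paB, (1, 1): 2 * pAB * pab + 2 * pAb * paB,
        (1, 0): 2 * pAb * pab, (0, 2): paB**2, (0, 1): 2 * paB * pab,
        (0, 0): pab**2,
    }
    return sum(np.log(max(probs[(int(x), int(y))], 1e-300)) for x, y in zip(g1, g2))


class TestEmTwoLocus:
    def test_identical_loci_perfect_ld(self, rng):
        g = rng.integers(0, 3, 200).astype(float)
        f = em_two_locus(g, g)
        pA = g.mean() / 2
        assert f[0] == pytest.approx(pA, abs=1e-9)
        assert f[3] == pytest.approx(1 - pA, abs=1e-9)
        assert f[1] == pytest.approx(0, abs=1e-9) and f[2] == pytest.approx(0, abs=1e-9)

    def test_no_double_het_equals_direct_counting(self):
        # genotype pairs with no (1,1) entries have unambiguous phase
        g1 = np.array([0, 0, 2, 2, 1, 1, 0, 2, 1], dtype=float)
        g2 = np.array([0, 2, 0, 2, 0, 2, 1, 1, 0], dtype=float)
        f = em_two_locus(g1, g2)
        # direct counting: each non-double-het genotype decomposes uniquely
        counts = np.zeros(4)  # AB, Ab, aB, ab
        for i, j in zip(g1.astype(int), g2.astype(int)):
            nAB = min(i, j)
            counts += [nAB, i - nAB, j - nAB, 2 - i - j + nAB]
        assert f == pytest.approx(counts / counts.sum(), abs=1e-12)

    def test_em_attains_grid_search_maximum(self, rng):
        """EM log-likelihood is a global max: never beaten by a dense 1-D
        grid along the margin-constrained ridge nor a coarse 3-simplex grid."""
        for _ in range(50):
            n = int(rng.integers(8, 31))
            f_true = rng.dirichlet([1, 1, 1, 1])
            g1, g2 = _genotypes_from_hap_freq(rng, f_true, n)
            if np.ptp(g1) == 0 or np.ptp(g2) == 0:
                continue
            est = em_two_locus(g1, g2)
            ll_em = _multinomial_loglik(est, g1, g2)
            pA, pB = g1.mean() / 2, g2.mean() / 2
            best = -np.inf
            for pAB in np.arange(max(0, pA + pB - 1), min(pA, pB) + 1e-12, 0.0005):
                f = np.array([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB])
                if f.min() < -1e-9:
                    continue
                best = max(best, _multinomial_loglik(f, g1, g2))
            step = 0.05
            for a in np.arange(0, 1 + 1e-9, step):
                for b in np.arange(0, 1 - a + 1e-9, step):
                    for c in np.arange(0, 1 - a - b + 1e-9, step):
                        best = max(
                            best,
                            _multinomial_loglik(np.array([a, b, c, 1 - a - b - c]), g1, g2),
                        )
            assert ll_em >= best - 1e-7


class TestR2:
    def test_identical_snps(self, rng):
        g = rng.integers(0, 3, 300).astype(float)
        assert r2(g, g) == pytest.approx(1.0, abs=1e-9)

    def test_independent_snps(self, rng):
        g1 = rng.binomial(2, 0.4, 10000).astype(float)
        g2 = rng.binomial(2, 0.3, 10000).astype(float)
        assert r2(g1, g2) < 0.01

    def test_monomorphic_is_zero(self, rng):
        g1 = np.zeros(100)
        g2 = rng.integers(0, 3, 100).astype(float)
        assert r2(g1, g2) == 0.0

    def test_allele_relabel_and_symmetry(self, rng):
        f = np.array([0.4, 0.2, 0.1, 0.3])
        g1, g2 = _genotypes_from_hap_freq(rng, f, 400)
        base = r2(g1, g2)
        assert r2(g2, g1) == pytest.approx(base, abs=1e-9)
        assert r2(2 - g1, g2) == pytest.approx(base, abs=1e-6)
        assert r2(g1, 2 - g2) == pytest.approx(base, abs=1e-6)

    def test_known_haplotype_frequencies(self, rng):
        """r² from unphased genotypes matches the analytic value of the
        sampling haplotype distribution within Monte-Carlo error."""
        f = np.array([0.5, 0.1, 0.1, 0.3])
        pA, pB = f[0] + f[1], f[0] + f[2]
        D = f[0] - pA * pB
        analytic = D * D / (pA * (1 - pA) * pB * (1 - pB))
        g1, g2 = _genotypes_from_hap_freq(rng, f, 20000)
        assert r2(g1, g2) == pytest.approx(analytic, abs=0.02)


class TestLdPairList:
    def _block_genotypes(self, seed):
        from gwastrat.simulate import SimConfig, gen_genotypes, gen_haplotype_pool

        cfg = SimConfig(
            n_snps=8, ld_block_size=4, ld_rho=0.9, seed=seed,
            n_per_stratum={"AFR_male": 600}, n_haplotypes=1200,
            maf_range=(0.2, 0.5),
        )
        return gen_genotypes(gen_haplotype_pool(cfg), cfg)

    def test_threshold_one_empty(self):
        G = self._block_genotypes(1)
        assert len(ld_pair_list(G, threshold=1.0)) == 0

    def test_threshold_zero_all_pairs(self):
        G = self._block_genotypes(2)
        assert len(ld_pair_list(G, threshold=0.0)) == 8 * 7 // 2

    def test_block_structure_recovered(self):
        G = self._block_genotypes(3)
        pairs = ld_pair_list(G, threshold=0.2)
        idx = {s: i for i, s in enumerate(G.snp_meta["snp_id"])}
        for _, row in pairs.iterrows():
            assert idx[row.snp_i] // 4 == idx[row.snp_j] // 4  # within-block only
        adjacent = {(f"snp{j:05d}", f"snp{j+1:05d}") for j in [0, 1, 2, 4, 5, 6]}
        found = {(r.snp_i, r.snp_j) for _, r in pairs.iterrows()}
        assert adjacent <= found

    def test_physical_window(self):
        G = self._block_genotypes(4)
        pairs = ld_pair_list(G, threshold=0.0, window_kb=2.0)
        pos = dict(zip(G.snp_meta["snp_id"], G.snp_meta["pos"]))
        assert all(abs(pos[r.snp_i] - pos[r.snp_j]) <= 2000 for _, r in pairs.iterrows())


class TestGeneMapping:
    def _meta(self, positions, chrom="2"):
        import pandas as pd

        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(len(positions))],
                "chrom": chrom,
                "pos": positions,
                "a1": "G",
                "a2": "A",
            }
        )

    def test_plus_strand_upstream_boundary(self):
        gene = GeneModel("g", "2", "+", 100_000, 110_000)
        meta = self._meta([80_000, 79_999, 120_000, 120_001])
        out = map_snps_to_gene(gene, meta)
        # [start-20k, end+10k] = [80 000, 120 000] inclusive
        assert out.mapped_snps == ["s0", "s2"]

    def test_minus_strand_window_arithmetic(self):
        # 5' of a - strand gene is the high-coordinate side: [90 000, 130 000]
        gene = GeneModel("g", "2", "-", 100_000, 110_000)
        meta = self._meta([125_000, 130_000, 130_001, 89_999, 90_000])
        out = map_snps_to_gene(gene, meta)
        assert set(out.mapped_snps) == {"s0", "s1", "s4"}

    def test_strand_agnostic_mode(self):
        gene = GeneModel("g", "2", "-", 100_000, 110_000)
        meta = self._meta([85_000, 125_000])
        out = map_snps_to_gene(gene, meta, strand_aware=False)
        assert out.mapped_snps == ["s0"]

    def test_window_clipped_at_one(self):
        gene = GeneModel("g", "2", "+", 5_000, 6_000)
        meta = self._meta([1, 100])
        out = map_snps_to_gene(gene, meta)
        assert set(out.mapped_snps) == {"s0", "s1"}

    def test_other_chromosome_excluded(self):
        gene = GeneModel("g", "2", "+", 100_000, 110_000)
        meta = self._meta([105_000], chrom="3")
        assert map_snps_to_gene(gene, meta).mapped_snps == []


class TestExtendByLd:
    def _setup(self, rng):
        g_a = rng.binomial(2, 0.3, 500).astype(float)
        g_b = g_a.copy()
        flip = rng.random(500) < 0.02  # near-duplicate: r2 ~ 0.95
        g_b[flip] = rng.binomial(2, 0.3, flip.sum())
        g_c = rng.binomial(2, 0.3, 500).astype(float)
        G = make_genotypes(np.column_stack([g_a, g_b, g_c]), chrom="2",
                           pos_start=100_000, pos_step=200_000)
        gene = GeneModel("g", "2", "+", 95_000, 105_000, mapped_snps=["s0"])
        return G, gene

    def test_strong_ld_snp_added(self, rng):
        G, gene = self._setup(rng)
        out = extend_by_ld(gene, G, r2_min=0.9)
        assert out.mapped_snps == ["s0", "s1"]

    def test_boundary_strictly_greater(self, rng):
        G, gene = self._setup(rng)
        rho = r2(G.dosage[:, 0], G.dosage[:, 1])
        # threshold equal to the observed r2 -> not added (strict >)
        out = extend_by_ld(gene, G, r2_min=rho)
        assert out.mapped_snps == ["s0"]

    def test_no_snp_above_threshold_unchanged(self, rng):
        G, gene = self._setup(rng)
        out = extend_by_ld(gene, G, r2_min=0.999)
        assert out.mapped_snps == ["s0"]

    def test_single_pass_idempotent(self, rng):
        G, gene = self._setup(rng)
        once = extend_by_ld(gene, G, r2_min=0.9)
        twice = extend_by_ld(once, G, r2_min=0.9)
        assert twice.mapped_snps == once.mapped_snps


def test_nck2_scale_locus_mapping(rng):
    """Window mapping plus one LD-extension pass recovers a 39-SNP gene set
    on a synthetic locus built to contain 39 mappable SNPs (30 inside the
    window, 9 outside but in near-perfect LD with inside SNPs)."""
    import pandas as pd

    n = 800
    inside = [rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float) for _ in range(30)]
    proxies = []
    for k in range(9):
        col = inside[k].copy()
        flip = rng.random(n) < 0.01
        col[flip] = rng.binomial(2, 0.3, flip.sum())
        proxies.append(col)
    unrelated = [rng.binomial(2, 0.3, n).astype(float) for _ in range(10)]
    pos_inside = list(100_000 + 500 * np.arange(30))
    pos_proxy = list(140_001 + 300 * np.arange(9))  # just past the 3' window
    pos_far = list(400_000 + 1000 * np.arange(10))
    dosage = np.column_stack(inside + proxies + unrelated)
    positions = pos_inside + pos_proxy + pos_far
    order = np.argsort(positions)
    meta = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(49)],
            "chrom": "2",
            "pos": positions,
            "a1": "G",
            "a2": "A",
        }
    )
    from gwastrat.datatypes import GenotypeMatrix

    G = GenotypeMatrix(dosage[:, order], meta.iloc[order].reset_index(drop=True))
    gene = GeneModel("NCK2-like", "2", "+", 105_000, 130_000)
    gene = map_snps_to_gene(gene, G.snp_meta)  # window [85 000, 140 000]
    assert len(gene.mapped_snps) == 30
    gene = extend_by_ld(gene, G, r2_min=0.9)
    assert len(gene.mapped_snps) == 39
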