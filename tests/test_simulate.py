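"""The synthetic cohort generator: copula LD, HWE by construction,
calibrated trait prevalences, planted effects, and the exact contingency
fixture."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from gwastrat.datatypes import TRAITS, validate_sample_table
from gwastrat.ld import r2
from gwastrat.qc import hwe_exact_pvalue
from gwastrat.simulate import (
    ConfigError,
    HaplotypePool,
    RiskSNP,
    SimConfig,
    gen_cohort,
    gen_genotypes,
    gen_haplotype_pool,
    gen_phenotypes,
    gen_scenario_table3,
    solve_intercept,
)


def _single_stratum(n, **kw):
    kw.setdefault("n_per_stratum", {"AFR_male": n})
    kw.setdefault("trait_prevalence", {"AFR_male": (0.621, 0.464, 0.254, 0.475, 0.082, 0.114)})
    kw.setdefault("age_mean_sd", {"AFR_male": (40.9, 8.2)})
    return SimConfig(**kw)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_snps", 0),
            ("maf_range", (0.0, 0.5)),
            ("maf_range", (0.6, 0.7)),
            ("ld_rho", 1.0),
            ("ld_block_size", 0),
            ("missing_rate", 1.5),
        ],
    )
    def test_bad_field_named_in_error(self, field, value):
        with pytest.raises(ConfigError) as err:
            SimConfig(**{field: value})
        assert field.split("_")[0] in str(err.value) or field in str(err.value)

    def test_bad_latent_corr(self):
        C = np.eye(len(TRAITS))
        C[0, 1] = 0.5  # asymmetric
        with pytest.raises(ConfigError):
            SimConfig(trait_latent_corr=C)

    def test_bad_prevalence(self):
        with pytest.raises(ConfigError):
            _single_stratum(100, trait_prevalence={"AFR_male": (1.2, 0.4, 0.2, 0.4, 0.1, 0.1)})


class TestDeterminism:
    def test_fixed_seed_bitwise_identical(self):
        cfg = _single_stratum(200, n_snps=20, seed=42)
        G1, S1, _ = gen_cohort(cfg)
        cfg2 = _single_stratum(200, n_snps=20, seed=42)
        G2, S2, _ = gen_cohort(cfg2)
        assert np.array_equal(G1.dosage, G2.dosage, equal_nan=True)
        pd.testing.assert_frame_equal(S1, S2)

    def test_scenario_fixture_deterministic(self):
        G1, S1 = gen_scenario_table3(seed=3)
        G2, S2 = gen_scenario_table3(seed=3)
        assert np.array_equal(G1.dosage, G2.dosage)
        pd.testing.assert_frame_equal(S1, S2)


class TestHaplotypePool:
    def test_frequencies_within_bounds(self):
        cfg = _single_stratum(10, n_snps=200, maf_range=(0.1, 0.4), seed=1)
        pool = gen_haplotype_pool(cfg)
        emp = pool.haplotypes.mean(axis=0)
        assert (pool.freq >= 0.1).all() and (pool.freq <= 0.4).all()
        assert np.abs(emp - pool.freq).max() < 0.05  # H=2000 sampling error

    def test_no_blocks_when_rho_zero(self):
        cfg = _single_stratum(5000, n_snps=40, ld_rho=0.0, ld_block_size=5,
                              maf_range=(0.2, 0.5), seed=2)
        G = gen_genotypes(gen_haplotype_pool(cfg), cfg)
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(100):
            i, j = rng.choice(40, size=2, replace=False)
            vals.append(r2(G.dosage[:, i], G.dosage[:, j]))
        assert np.mean(vals) < 0.05

    def test_block_size_one_all_independent(self):
        cfg = _single_stratum(4000, n_snps=12, ld_rho=0.9, ld_block_size=1,
                              maf_range=(0.2, 0.5), seed=3)
        G = gen_genotypes(gen_haplotype_pool(cfg), cfg)
        vals = [
            r2(G.dosage[:, i], G.dosage[:, j])
            for i in range(12) for j in range(i + 1, 12)
        ]
        assert np.mean(vals) < 0.02 and max(vals) < 0.05

    def test_within_block_r2_matches_copula_oracle(self):
        """Empirical haplotype r² vs the analytic two-locus distribution of
        the thresholded bivariate normal (orthant probability oracle)."""
        cfg = _single_stratum(10, n_snps=2, ld_rho=0.9, ld_block_size=2,
                              n_haplotypes=20_000, maf_range=(0.2, 0.5), seed=4)
        pool = gen_haplotype_pool(cfg)
        f1, f2 = pool.freq
        t1, t2 = stats.norm.ppf(1 - f1), stats.norm.ppf(1 - f2)
        # P(Z1 > t1, Z2 > t2) with corr rho: upper orthant of the BVN
        p11 = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, 0.9], [0.9, 1]]
        ).cdf([-t1, -t2])
        D = p11 - f1 * f2
        analytic = D * D / (f1 * (1 - f1) * f2 * (1 - f2))
        h = pool.haplotypes.astype(float)
        emp = np.corrcoef(h[:, 0], h[:, 1])[0, 1] ** 2
        assert emp == pytest.approx(analytic, abs=0.03)

    def test_monomorphic_pool_column_gives_zero_genotypes(self):
        cfg = _single_stratum(50, n_snps=2, seed=5)
        pool = gen_haplotype_pool(cfg)
        pool.haplotypes[:, 0] = 0
        G = gen_genotypes(pool, cfg)
        assert np.all(G.dosage[:, 0] == 0)


class TestGenotypes:
    def test_hwe_pvalues_uniform_over_null_snps(self):
        """HWE holds by construction: exact-test P values across many
        independent SNPs at n=5000 are uniform (KS at the 1% level)."""
        cfg = _single_stratum(5000, n_snps=200, ld_rho=0.0, ld_block_size=1,
                              maf_range=(0.1, 0.5), n_haplotypes=4000, seed=6)
        G = gen_genotypes(gen_haplotype_pool(cfg), cfg)
        counts = G.genotype_counts()
        pvals = [hwe_exact_pvalue(*c) for c in counts]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_rate_honoured(self):
        cfg = _single_stratum(500, n_snps=50, missing_rate=0.1, seed=7)
        G = gen_genotypes(gen_haplotype_pool(cfg), cfg)
        assert np.isnan(G.dosage).mean() == pytest.approx(0.1, abs=0.01)


class TestPhenotypes:
    def test_null_model_traits_uncorrelated(self):
        cfg = _single_stratum(
            10_000, n_snps=2, seed=8,
            trait_latent_corr=np.eye(len(TRAITS)),
        )
        _, S, _ = gen_cohort(cfg)
        Y = S[list(TRAITS)].to_numpy(float)
        corr = np.corrcoef(Y.T)
        off = corr[~np.eye(len(TRAITS), dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_latent_correlation_induces_comorbidity(self):
        cfg = _single_stratum(10_000, n_snps=2, seed=9)  # default rho 0.3
        _, S, _ = gen_cohort(cfg)
        Y = S[list(TRAITS)].to_numpy(float)
        corr = np.corrcoef(Y.T)
        off = corr[~np.eye(len(TRAITS), dtype=bool)]
        assert off.mean() > 0.1

    def test_target_prevalence_recovered(self):
        """Marginal opiates prevalence 8.2% within 3 binomial SEs at n=10 000."""
        cfg = _single_stratum(10_000, n_snps=2, seed=10)
        _, S, _ = gen_cohort(cfg)
        prev = S["opiates"].mean()
        se = np.sqrt(0.082 * (1 - 0.082) / 10_000)
        assert abs(prev - 0.082) <= 3 * se

    def test_planted_rare_variant_enriches_cases(self):
        """Case/control allele frequency of the planted SNP matches the
        analytic expectation under the logistic penetrance model."""
        beta = np.zeros(len(TRAITS))
        beta[TRAITS.index("opiates")] = np.log(13.87)
        cfg = _single_stratum(
            10_000, n_snps=5, seed=11,
            risk_snp=RiskSNP(2, beta, maf=0.016),
        )
        G, S, pool = gen_cohort(cfg)
        f = pool.haplotypes[:, 2].mean()  # realized pool frequency
        pg = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
        c = solve_intercept(0.082, np.log(13.87), pg)
        pen = expit(c + np.log(13.87) * np.arange(3))
        case_maf_analytic = (pg * pen) @ np.arange(3) / (2 * (pg * pen).sum())
        ctrl_maf_analytic = (pg * (1 - pen)) @ np.arange(3) / (2 * (pg * (1 - pen)).sum())
        y = S["opiates"].to_numpy(float)
        g = G.dosage[:, 2]
        case_maf = g[y == 1].sum() / (2 * (y == 1).sum())
        ctrl_maf = g[y == 0].sum() / (2 * (y == 0).sum())
        n_case = (y == 1).sum()
        se_case = np.sqrt(case_maf_analytic * (1 - case_maf_analytic) / (2 * n_case))
        assert case_maf > 3 * ctrl_maf  # strong enrichment
        assert abs(case_maf - case_maf_analytic) <= 4 * se_case
        assert ctrl_maf == pytest.approx(ctrl_maf_analytic, abs=0.005)

    def test_sample_table_schema(self):
        cfg = SimConfig(n_snps=2, seed=12, n_per_stratum={
            "AFR_male": 30, "AFR_female": 30, "EUR_male": 30, "EUR_female": 30})
        _, S, _ = gen_cohort(cfg)
        validate_sample_table(S)
        assert sorted(S["ancestry"].unique()) == ["AFR", "EUR"]


class TestScenarioFixture:
    def test_case_control_totals(self, table3):
        _, S = table3
        y = S["opiates"]
        assert int(y.sum()) == 44 and int((1 - y).sum()) == 491

    def test_allele_counts_and_no_homozygotes(self, table3):
        G, S = table3
        g = G.dosage[:, 0]
        assert g.sum() == 17 and len(g) == 535
        assert (g == 2).sum() == 0  # zero GG genotypes
        assert G.snp_meta.loc[0, "a1"] == "G"

    def test_exact_genotype_by_status_counts(self, table3):
        G, S = table3
        g = G.dosage[:, 0]
        y = S["opiates"].to_numpy()
        assert ((y == 1) & (g == 1)).sum() == 9 and ((y == 1) & (g == 0)).sum() == 35
        assert ((y == 0) & (g == 1)).sum() == 8 and ((y == 0) & (g == 0)).sum() == 483
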