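"""Synthetic genotype/phenotype generator with the statistical structure the
downstream analysis assumes.

Genotypes: haplotypes are drawn from a latent Gaussian copula — within an LD
block of ``ld_block_size`` SNPs the latent variables follow an AR(1) process
with coefficient ``ld_rho``; thresholding at the allele-frequency quantile
produces binary haplotypes, and each genotype is the sum of two haplotypes
drawn independently from the pool, so Hardy-Weinberg equilibrium holds by
construction within every stratum.  The two-locus haplotype distribution of
this construction is analytically available (orthant probabilities of a
bivariate normal), which makes the generator exactly checkable.

Phenotypes: the six lifetime-dependence diagnoses are Bernoulli with a
per-stratum, per-trait logit

    logit P(Y_ij = 1) = c_sj + beta_j * g_i(risk) + age_beta_j * age_std,

with the intercept c_sj solved numerically so the *marginal* prevalence
matches the configured per-stratum target even in the presence of a planted
genetic effect.  Cross-trait comorbidity is induced by drawing the
Bernoulli uniforms from a Gaussian copula with correlation
``trait_latent_corr``.

The default configuration emulates the stratified substance-dependence
case-control cohort the pipeline is designed for: four ancestry x sex
strata of sizes 535 / 568 / 1131 / 1393 with the per-stratum trait
prevalences and age distributions of that cohort.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .datatypes import TRAITS, DataError, GenotypeMatrix
from .io import write_plink_text  # noqa: F401  (re-exported convenience)

#: Stratum labels in generation order.
STRATUM_LABELS = ("AFR_male", "AFR_female", "EUR_male", "EUR_female")

_ALLELE_PAIRS = (("G", "A"), ("C", "T"), ("A", "C"), ("T", "G"))


class ConfigError(ValueError):
    """A SimConfig field is out of its valid domain."""


@dataclass
class RiskSNP:
    """A planted risk variant: SNP index plus per-trait log odds ratios.

    ``maf``, if set, pins the variant's population allele frequency (its
    latent threshold is set at that quantile, overriding the draw from
    ``maf_range`` while keeping it inside the block copula).
    """

    index: int
    beta: np.ndarray  # length 6, trait order as datatypes.TRAITS
    maf: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(TRAITS),):
            raise ConfigError(
                f"risk_snp.beta must have length {len(TRAITS)} (one per trait)"
            )
        if self.maf is not None and not 0 < self.maf <= 0.5:
            raise ConfigError("risk_snp.maf must be in (0, 0.5]")


def _exchangeable_corr(p: int, rho: float) -> np.ndarray:
    C = np.full((p, p), rho)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic cohort."""

    n_per_stratum: dict = field(
        default_factory=lambda: {
            "AFR_male": 535,
            "AFR_female": 568,
            "EUR_male": 1131,
            "EUR_female": 1393,
        }
    )
    n_snps: int = 100
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.8
    trait_prevalence: dict = field(
        default_factory=lambda: {
            # alcohol, cocaine, marijuana, nicotine, opiates, other
            "AFR_male": (0.621, 0.464, 0.254, 0.475, 0.082, 0.114),
            "AFR_female": (0.394, 0.363, 0.137, 0.477, 0.062, 0.065),
            "EUR_male": (0.623, 0.273, 0.252, 0.467, 0.099, 0.180),
            "EUR_female": (0.311, 0.125, 0.087, 0.411, 0.048, 0.094),
        }
    )
    risk_snp: RiskSNP | None = None
    trait_latent_corr: np.ndarray = field(
        default_factory=lambda: _exchangeable_corr(len(TRAITS), 0.3)
    )
    age_mean_sd: dict = field(
        default_factory=lambda: {
            "AFR_male": (40.9, 8.2),
            "AFR_female": (39.7, 6.7),
            "EUR_male": (38.7, 10.3),
            "EUR_female": (38.2, 9.1),
        }
    )
    age_beta: np.ndarray = field(default_factory=lambda: np.zeros(len(TRAITS)))
    n_haplotypes: int = 2000
    missing_rate: float = 0.0
    chrom: str = "2"
    pos_start: int = 105_700_000
    pos_step: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.trait_latent_corr = np.asarray(self.trait_latent_corr, dtype=float)
        self.age_beta = np.asarray(self.age_beta, dtype=float)
        self.validate()

    def validate(self) -> None:
        for label in self.n_per_stratum:
            if label not in STRATUM_LABELS:
                raise ConfigError(f"n_per_stratum: unknown stratum label {label!r}")
        if any(n < 0 for n in self.n_per_stratum.values()):
            raise ConfigError("n_per_stratum: counts must be non-negative")
        if self.n_snps < 1:
            raise ConfigError("n_snps: must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range: bounds must satisfy 0 < low <= high <= 0.5")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size: must be >= 1")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho: must be in [0, 1)")
        for label, prev in self.trait_prevalence.items():
            if label not in STRATUM_LABELS:
                raise ConfigError(f"trait_prevalence: unknown stratum label {label!r}")
            prev = np.asarray(prev, dtype=float)
            if prev.shape != (len(TRAITS),) or not ((prev > 0) & (prev < 1)).all():
                raise ConfigError(
                    f"trait_prevalence[{label}]: needs {len(TRAITS)} values in (0,1)"
                )
        C = self.trait_latent_corr
        p = len(TRAITS)
        if C.shape != (p, p) or not np.allclose(C, C.T):
            raise ConfigError("trait_latent_corr: must be symmetric p x p")
        if not np.allclose(np.diag(C), 1.0):
            raise ConfigError("trait_latent_corr: diagonal must be 1")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ConfigError("trait_latent_corr: must be positive semi-definite")
        if self.risk_snp is not None and not 0 <= self.risk_snp.index < self.n_snps:
            raise ConfigError("risk_snp.index: out of range")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate: must be in [0, 1)")
        if self.n_haplotypes < 2:
            raise ConfigError("n_haplotypes: must be >= 2")
        if self.age_beta.shape != (len(TRAITS),):
            raise ConfigError("age_beta: one coefficient per trait required")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_stratum.values()))

    def sub_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        # crc32 is stable across processes (str.hash is salted per run)
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return np.random.default_rng(ss)


@dataclass
class HaplotypePool:
    haplotypes: np.ndarray  # H x n_snps, values in {0,1}
    snp_meta: pd.DataFrame
    freq: np.ndarray  # configured allele-1 frequency per SNP
    block_id: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes)
        if h.size and not np.isin(h, (0, 1)).all():
            raise DataError("haplotype entries must be 0/1")
        pos = self.snp_meta["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise DataError("positions must be strictly increasing")


def gen_haplotype_pool(cfg: SimConfig) -> HaplotypePool:
    """Draw the haplotype pool from the block-AR(1) Gaussian copula."""
    cfg.validate()
    rng = cfg.sub_rng("haplotypes")
    m, H = cfg.n_snps, cfg.n_haplotypes
    freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    if cfg.risk_snp is not None and cfg.risk_snp.maf is not None:
        freq[cfg.risk_snp.index] = cfg.risk_snp.maf
    block = np.arange(m) // cfg.ld_block_size
    z = np.empty((H, m))
    eps = rng.standard_normal((H, m))
    for j in range(m):
        if j == 0 or block[j] != block[j - 1]:
            z[:, j] = eps[:, j]
        else:
            z[:, j] = cfg.ld_rho * z[:, j - 1] + np.sqrt(1 - cfg.ld_rho**2) * eps[:, j]
    thresh = stats.norm.ppf(1 - freq)  # P(Z > t) = freq
    hap = (z > thresh[None, :]).astype(np.int8)
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(m)],
            "chrom": cfg.chrom,
            "pos": cfg.pos_start + cfg.pos_step * np.arange(m),
            "a1": [_ALLELE_PAIRS[j % 4][0] for j in range(m)],
            "a2": [_ALLELE_PAIRS[j % 4][1] for j in range(m)],
        }
    )
    return HaplotypePool(hap, meta, freq, block)


def gen_genotypes(pool: HaplotypePool, cfg: SimConfig) -> GenotypeMatrix:
    """Sum two independently drawn pool haplotypes per individual.

    HWE holds by construction.  Missing calls (NaN) are injected uniformly
    at ``cfg.missing_rate`` if configured.
    """
    if pool.haplotypes.shape[0] == 0:
        raise DataError("empty haplotype pool")
    rng = cfg.sub_rng("genotypes")
    n = cfg.n_total
    H = pool.haplotypes.shape[0]
    i1 = rng.integers(0, H, size=n)
    i2 = rng.integers(0, H, size=n)
    dosage = (pool.haplotypes[i1] + pool.haplotypes[i2]).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    ids = _sample_ids(cfg)
    return GenotypeMatrix(dosage, pool.snp_meta.copy(), ids)


def _sample_ids(cfg: SimConfig) -> np.ndarray:
    ids = []
    for label in STRATUM_LABELS:
        n = cfg.n_per_stratum.get(label, 0)
        ids += [f"{label}_{i:05d}" for i in range(n)]
    return np.array(ids, dtype=object)


def _gauss_hermite(n_nodes: int = 31):
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    return x, w / w.sum()


def solve_intercept(
    prev: float, beta: float, geno_probs: np.ndarray, age_beta: float = 0.0
) -> float:
    """Intercept c with marginal prevalence ``prev`` under the logit model.

    Averages expit(c + beta*g + age_beta*a) over the genotype distribution
    and a standard-normal standardized age (Gauss-Hermite quadrature).
    """
    g = np.array([0.0, 1.0, 2.0])
    if age_beta == 0.0:
        def marginal(c):
            return float(np.dot(geno_probs, expit(c + beta * g)) - prev)
    else:
        nodes, wts = _gauss_hermite()
        def marginal(c):
            vals = expit(c + beta * g[:, None] + age_beta * nodes[None, :])
            return float(geno_probs @ (vals @ wts) - prev)
    return brentq(marginal, -40.0, 40.0, xtol=1e-12)


def gen_phenotypes(
    G: GenotypeMatrix, cfg: SimConfig, pool: HaplotypePool | None = None
) -> pd.DataFrame:
    """Generate the phenotype/covariate table for a generated cohort.

    Requires the genotype rows to follow the stratum blocks of
    ``cfg.n_per_stratum`` (as produced by :func:`gen_genotypes`).  If the
    pool is supplied its configured allele frequency calibrates the
    intercepts; otherwise the empirical frequency in ``G`` is used.
    """
    if G.n_samples != cfg.n_total:
        raise DataError("genotype rows do not match configured strata sizes")
    rng = cfg.sub_rng("phenotypes")
    p = len(TRAITS)
    beta = np.zeros(p)
    risk_dosage = np.zeros(G.n_samples)
    geno_probs = np.array([1.0, 0.0, 0.0])
    if cfg.risk_snp is not None:
        beta = cfg.risk_snp.beta
        risk_dosage = np.nan_to_num(G.dosage[:, cfg.risk_snp.index])
        f = (
            float(pool.freq[cfg.risk_snp.index])
            if pool is not None
            else float(np.nanmean(G.dosage[:, cfg.risk_snp.index]) / 2.0)
        )
        geno_probs = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])

    L = np.linalg.cholesky(
        cfg.trait_latent_corr + 1e-10 * np.eye(p)
    )
    rows_sex, rows_anc, rows_age = [], [], []
    traits = np.empty((G.n_samples, p), dtype=int)
    offset = 0
    for label in STRATUM_LABELS:
        n = cfg.n_per_stratum.get(label, 0)
        if n == 0:
            continue
        ancestry, sex = label.split("_")
        mean, sd = cfg.age_mean_sd[label]
        age = rng.normal(mean, sd, size=n)
        age_std = (age - mean) / sd
        prev = np.asarray(cfg.trait_prevalence[label], dtype=float)
        intercepts = np.array(
            [
                solve_intercept(prev[j], beta[j], geno_probs, cfg.age_beta[j])
                for j in range(p)
            ]
        )
        logits = (
            intercepts[None, :]
            + np.outer(risk_dosage[offset : offset + n], beta)
            + np.outer(age_std, cfg.age_beta)
        )
        probs = expit(logits)
        latent = rng.standard_normal((n, p)) @ L.T
        u = stats.norm.cdf(latent)
        traits[offset : offset + n] = (u < probs).astype(int)
        rows_sex += [sex] * n
        rows_anc += [ancestry] * n
        rows_age.append(age)
        offset += n
    table = pd.DataFrame({"sample_id": G.sample_ids})
    table["sex"] = rows_sex
    table["ancestry"] = rows_anc
    table["age"] = np.concatenate(rows_age)
    for j, t in enumerate(TRAITS):
        table[t] = traits[:, j]
    return table


def gen_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, HaplotypePool]:
    """Convenience wrapper: pool -> genotypes -> phenotypes."""
    pool = gen_haplotype_pool(cfg)
    G = gen_genotypes(pool, cfg)
    S = gen_phenotypes(G, cfg, pool)
    return G, S, pool


def gen_scenario_table3(seed: int = 0) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Exact single-stratum fixture for the rare-risk-variant contingency
    analysis.

    535 African-ancestry men and one SNP whose opiates case/control
    genotype counts are placed exactly (not sampled):
    cases 35 AA / 9 AG / 0 GG, controls 483 AA / 8 AG / 0 GG.
    The overall minor (G) allele count is therefore 17 of 1070.
    Only ages and the row order are randomised.
    """
    rng = np.random.default_rng(seed)
    dosage = np.concatenate(
        [
            np.zeros(35),  # case AA
            np.ones(9),  # case AG
            np.zeros(483),  # control AA
            np.ones(8),  # control AG
        ]
    )
    opiates = np.concatenate([np.ones(44), np.zeros(491)]).astype(int)
    order = rng.permutation(535)
    dosage, opiates = dosage[order], opiates[order]
    meta = pd.DataFrame(
        {
            "snp_id": ["rs2377339"],
            "chrom": ["2"],
            "pos": [105_823_723],
            "a1": ["G"],
            "a2": ["A"],
        }
    )
    ids = np.array([f"AFR_male_{i:05d}" for i in range(535)], dtype=object)
    G = GenotypeMatrix(dosage[:, None], meta, ids)
    table = pd.DataFrame(
        {
            "sample_id": ids,
            "sex": "male",
            "ancestry": "AFR",
            "age": rng.normal(40.9, 8.2, size=535),
        }
    )
    for t in TRAITS:
        table[t] = opiates if t == "opiates" else 0
    return G, table


def gen_gene_annotation(
    cfg: SimConfig, genes_per_block: int = 1, gene_halfwidth: int = 3_000
) -> pd.DataFrame:
    """Gene annotation covering the simulated SNP blocks.

    One gene per LD block by default, centred on the block, alternating
    strand.  Returns a DataFrame (gene_id, chrom, strand, start, end).
    """
    n_blocks = int(np.ceil(cfg.n_snps / cfg.ld_block_size))
    rows = []
    for b in range(n_blocks):
        first = b * cfg.ld_block_size
        last = min(cfg.n_snps, first + cfg.ld_block_size) - 1
        centre = cfg.pos_start + cfg.pos_step * (first + last) // 2
        rows.append(
            {
                "gene_id": f"GENE{b:03d}",
                "chrom": cfg.chrom,
                "strand": "+" if b % 2 == 0 else "-",
                "start": max(1, centre - gene_halfwidth),
                "end": centre + gene_halfwidth,
            }
        )
    return pd.DataFrame(rows)
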