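# Methods

## Study design being emulated

The pipeline targets a stratified case-control association study of
substance dependence: subjects carry six binary lifetime-dependence
diagnoses (alcohol, cocaine, marijuana, nicotine, opiates, other drugs),
sex, ancestry group and age, and are analysed separately within the four
ancestry × sex strata to avoid population-structure confounding.  The
reference stratum sizes are 535 / 568 / 1131 / 1393 (African-ancestry men
and women, European-ancestry men and women), and the reference planted
signal is a rare variant (MAF 1.6%) with a per-allele odds ratio of 13.87
on the opiates trait in the 535-subject stratum — the regime the
implementation choices below are tuned for.

## Quality control

Defaults: exclude samples with genotype call rate < 90%, SNPs with
MAF < 1%, and SNPs with Hardy–Weinberg exact P ≤ 10⁻⁴.  Boundary semantics
are literal (call rate exactly 90% and MAF exactly 1% are retained; HWE P
exactly 10⁻⁴ is removed).  The HWE test is the exact conditional test —
the probability of the heterozygote count given allele counts,
P(n_Aa | n, n_A) ∝ n!/(n_AA! n_Aa! n_aa!)·2^{n_Aa}, summed over all
configurations no more probable than the observed one — rather than the
chi-square approximation, which is unreliable at MAF ≈ 1.6%.  HWE is
evaluated per stratum in the pipeline (testing pooled across ancestries
would reject merely for allele-frequency differences between groups, the
very confounding the stratification removes); nothing in the study design
fixes this choice, so it is switchable.  Filter order is call rate → MAF →
HWE; each filter is idempotent and the QC report records removals per step.

## Single-SNP association

The allelic test is the 1-df Pearson chi-square on the 2×2 allele-count
table without continuity correction — with the Yates correction the exact
fixture below would not reproduce its published-scale P.  OR is the
cross-product ratio; a zero cell triggers the Haldane–Anscombe +0.5
correction with a flag.  The logistic test (additive dosage coding,
optional covariates) is fitted by Newton/IRLS via statsmodels with
log-likelihood tolerance 10⁻⁸ and at most 100 iterations; |slope| > 10 is
flagged as near-separation and non-convergence yields a flagged result with
a missing P rather than a silent number.  Per-stratum scans run the
logistic model without covariates; covariate adjustment (sex, ancestry) is
for pooled analyses.  Missing genotypes are dropped per marker.

On the exact fixture (counts 35/9/0 vs 483/8/0) the allelic P is
1.33×10⁻¹¹ while the logistic Wald P is 1.10×10⁻⁷.  The gap is expected:
with 17 carriers and a slope near log 13.87 the Wald standard error is
inflated (the quadratic approximation to the likelihood degrades far from
the null), so the Wald test is conservative exactly where the allelic
chi-square is strong.

## LD and gene mapping

r² comes from maximum-likelihood two-locus haplotype frequencies estimated
from unphased genotypes by EM over the double-heterozygote phase ambiguity
(tolerance 10⁻¹⁰, ≤ 1000 iterations).  The observed-data likelihood can be
bimodal in the double-het split, so the EM runs from coupling-, neutral-
and repulsion-leaning starts and keeps the highest-likelihood solution; a
grid-search audit over the frequency simplex confirms global optimality on
small datasets.  Monomorphic input is defined to have r² = 0.

SNPs map to a gene from a strand-aware window: 20 kb 5′ upstream and 10 kb
3′ downstream of the gene body, boundaries inclusive, clipped at position 1.
For a − strand gene the 5′ side is the higher-coordinate side; a
strand-agnostic mode (always left 20 kb / right 10 kb) is available because
annotation conventions differ.  One LD-extension pass then adds SNPs with
r² > 0.9 to any *initially* mapped SNP; extension is deliberately a single
pass (transitive closure is unbounded) and idempotent.  The r² > 0.2 pair
list consumed by the gene-level test is computed per analysis stratum by
default (switchable), matching the per-stratum inferential frame.

## Gene-level combination

P_G = min_j m_e·P₍ⱼ₎/m_e(j) over the ascending SNP P values, capped at 1,
with the effective number of tests m_e = m − Σ I(λᵢ>1)(λᵢ−1) from the
eigenvalues of the SNP P-value correlation matrix, and m_e(j) the same
functional on the top-j submatrix (re-eigendecomposed per j; O(m⁴) worst
case is accepted at the m ≤ few-hundred scale).  Ties among equal P values
break by genomic position for a deterministic m_e(j) sequence.  Under an
identity correlation the rule reduces exactly to the Simes test.

The P-value correlation is derived from the pairwise genotype correlation
r.  The default mapping is the *exact* correlation between two 1-df
two-sided P values whose score statistics are bivariate normal with
correlation r — a fixed, parameter-free smooth function of |r| computed
once by Gauss–Hermite quadrature and interpolated.  The naive |r| mapping
(available as a pluggable alternative) overstates corr(P_i, P_j) at
moderate LD; since smaller m_e *shrinks* the Simes penalty, that
approximation is anti-conservative — measured at type-I 0.067 at nominal
0.05 on LD-structured null genes, versus 0.050 for the quadrature mapping.
That measurement drove the default.  The matrix is symmetrised, given a
unit diagonal, and eigenvalue-clipped to the nearest PSD matrix when
needed.  Significance uses fixed genome-wide thresholds: 5×10⁻⁸ per SNP and
0.05/20 000 = 2.5×10⁻⁶ per gene; no FDR, matching the threshold-based
inferential frame.

## Generalized Kendall's tau

U = C(n,2)⁻¹ Σ_{i<j} (Yᵢ−Yⱼ)(gᵢ−gⱼ), computed through the O(np) identity
Σ_{i<j}(Yᵢ−Yⱼ)(gᵢ−gⱼ) = n ΣYᵢgᵢ − (ΣY)(Σg).  The null is conditional on
the observed phenotypes: under uniformly random permutation of g, U has
mean 0 and covariance n²/((n−1)·C(n,2)²) · S_Y · s_g with S_Y the centered
trait cross-product matrix and s_g the centered genotype sum of squares —
the classical permutation moments of a linear statistic, verified against
permutation oracles entrywise.  The statistic Uᵀ Σ⁺ U uses a pseudoinverse
with eigenvalue cutoff 10⁻¹⁰·λ_max, df = rank(Σ); P comes from chi-square
(default) or from the permutation distribution (Σ is permutation-invariant,
so one pseudoinverse serves all permutations).  Degenerate inputs (constant
g, constant trait) reduce rank; zero rank returns P = 1 with a flag.
Missing traits are handled complete-case per analysis.

The covariate-adjusted variant weights pairs by a Gaussian kernel on
standardized covariate distance, w_ij = exp(−½ Σ_q d²_ijq), bandwidth per
covariate by Silverman's rule (0.9·min(sd, IQR/1.349)·n^{−1/5}) on the
standardized scale; U_w = (Σw)⁻¹ Σ w_ij (Yᵢ−Yⱼ)(gᵢ−gⱼ).  Constant
covariates contribute nothing to the distance, so the weighted statistic
reduces exactly to the unweighted one when covariates are uninformative.
Inference is by permutation of g with weights held fixed; the statistic is
the quadratic form in the permutation covariance of U_w.  This kernel
weighting is this package's own construction satisfying that reduction
contract — it is a documented stand-in for covariate-weighted U statistics
whose exact weight construction is not reproduced here, and it is validated
behaviourally: with an uninformative covariate the adjusted and unadjusted
P values agree in distribution, and in a strongly confounded scenario
(covariate driving both allele frequency and trait prevalence) the
unadjusted test rejects at > 3× nominal while the adjusted test stays
within 1.5× nominal.  The codependence analysis uses all six traits and
analytic P by default; both are switchable.

## Synthetic data generator

Haplotypes come from a latent Gaussian copula: within an LD block of
`ld_block_size` SNPs the latent variables follow an AR(1) process with
coefficient `ld_rho` (default blocks of 5, ρ = 0.8); thresholding at the
allele-frequency quantile gives binary haplotypes, and a genotype is the
sum of two haplotypes drawn independently from a pool (default 2000), so
HWE holds by construction within every stratum.  The two-locus haplotype
distribution is an orthant probability of a bivariate normal, making the
generator exactly auditable.  SNP allele frequencies are uniform on
`maf_range`; a planted risk SNP can pin its frequency exactly.

Traits are Bernoulli with logit = stratum-trait intercept + β_j·dosage +
age term, the intercept solved numerically (Brent + Gauss–Hermite) so the
*marginal* prevalence matches the configured per-stratum target even with a
planted effect.  Default prevalences and ages are the reference cohort's
per-stratum values (e.g. opiates 8.2% among African-ancestry men, age
40.9 ± 8.2 y).  Comorbidity comes from a Gaussian copula on the Bernoulli
uniforms with exchangeable latent correlation 0.3 by default — a
single-factor stand-in chosen to give trait–trait correlations of the
modest positive size typical of dependence comorbidity; the matrix is fully
configurable.  Missingness is off by default (a uniform rate exercises QC).
All randomness derives from one integer seed through fixed, stable
sub-streams; identical configuration yields bitwise-identical datasets.

What the generator does *not* emulate: realistic human LD maps and
recombination, allele-frequency differences between ancestries, X
chromosome, genotyping batch artefacts, relatedness/duplicates, and
ascertainment (it simulates prospective strata, not case-control sampled
ones).  Passing tests therefore certify the statistical machinery under the
assumed structure, not robustness to those real-data complications.

An exact contingency fixture places (not samples) the rare-variant
genotype-by-status counts 35/9/0 vs 483/8/0 in 535 subjects, so the
contingency summaries — allele table (9, 79, 8, 974), OR 13.87, allelic
P 1.33×10⁻¹¹, pooled MAF 1.59%, control carriers 1.63% — are deterministic
anchors.

## Calibration and recovery studies

Problem sizes were chosen to give tight Monte-Carlo error at desk scale:
the analytic tau test is calibrated over 2000 null replicates (n = 500,
p = 6 correlated traits); the gene-level P over 5000 null genes (8 SNPs in
two LD blocks, n = 800); the HWE implementation is checked against
exact-rational enumeration for all 23 425 genotype tables with n ≤ 50; and
recovery plants the reference variant (MAF 1.6%, per-allele OR 13.87 on
opiates, n = 535, 20 genes × 5 SNPs) over 200 replicates.

Recovery is measured by the logistic MLE slope, the estimator of the
planted per-allele log-OR: over 1000 replicates its mean is 2.642 against
the target log 13.87 = 2.630 (essentially unbiased).  The allelic 2×2
log-OR is *not* an unbiased estimator of the conditional per-allele log-OR
in this regime — when cases are strongly enriched for a rare allele the
allelic OR is attenuated by the factor [(2N₁−H₁)/(N₁−H₁)]⁻¹-type terms
(measured mean 2.560, ≈ −0.07) — so it is reported alongside but not used
as the recovery criterion.

## Known limitations

- The gene-level P-value correlation assumes bivariate-normal score
  statistics; for very rare variants the normal approximation of the
  allelic chi-square weakens, and P_G inherits whatever miscalibration the
  per-SNP test has.
- The kernel-weighted adjusted tau uses global permutation of g, which
  breaks the g–covariate link under the null being simulated; calibration
  is demonstrated empirically, not derived.
- Haplotype-level association testing is out of scope; the LD machinery
  stops at pairwise r².
- The pipeline is single-threaded and desk-scale (10³–10⁴ SNPs); it is not
  tuned for 10⁶-SNP genomes.
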