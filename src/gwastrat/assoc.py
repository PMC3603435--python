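"""Single-SNP case-control association tests.

The allelic test is the 1-df Pearson chi-square on the 2x2 allele-count
table, without continuity correction, with the odds ratio as the
cross-product ratio.  The logistic test fits an additive (0/1/2 dosage)
logistic regression and reports the Wald P for the dosage slope; covariates
are optional.  Tables with a zero cell get the Haldane-Anscombe +0.5
correction for the odds ratio, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .datatypes import ContingencyTable2x2, DataError


@dataclass
class SnpAssocResult:
    snp_id: str = ""
    test: str = ""  # "allelic" or "logistic"
    statistic: float = np.nan
    p_value: float = np.nan
    odds_ratio: float = np.nan
    maf_case: float = np.nan
    maf_control: float = np.nan
    maf_overall: float = np.nan
    n_case: int = 0
    n_control: int = 0
    flags: list = field(default_factory=list)


def _clean_pair(genotypes, status):
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(status, dtype=float)
    if g.shape != y.shape:
        raise DataError("genotype and status vectors differ in length")
    keep = ~(np.isnan(g) | np.isnan(y))
    g, y = g[keep], y[keep]
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("status must be binary")
    return g, y


def allele_table(genotypes, status) -> ContingencyTable2x2:
    """Build the case/control allele-count table from dosages.

    Missing dosages are dropped pairwise.  ``a`` is the summed case dosage
    (minor-allele count), ``b`` the remaining case alleles, likewise
    ``c``/``d`` for controls.
    """
    g, y = _clean_pair(genotypes, status)
    n_case = int((y == 1).sum())
    n_control = int((y == 0).sum())
    if n_case == 0 or n_control == 0:
        raise DataError("need at least one case and one control")
    a = float(g[y == 1].sum())
    c = float(g[y == 0].sum())
    return ContingencyTable2x2(a, 2 * n_case - a, c, 2 * n_control - c)


def odds_ratio(t: ContingencyTable2x2) -> tuple[float, bool]:
    """Cross-product odds ratio ``ad/(bc)``.

    Returns ``(or, corrected)``; a table with any zero cell gets the
    Haldane-Anscombe +0.5 added to all four cells and ``corrected=True``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = t.has_zero_cell()
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), corrected


def allelic_test(t: ContingencyTable2x2) -> SnpAssocResult:
    """1-df Pearson chi-square on the allele table (no continuity correction)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.total
    if n == 0:
        raise DataError("empty contingency table")
    res = SnpAssocResult(test="allelic", n_case=int((a + b) // 2), n_control=int((c + d) // 2))
    margins = (a + b, c + d, a + c, b + d)
    orval, corrected = odds_ratio(t)
    res.odds_ratio = orval
    if corrected:
        res.flags.append("zero_cell_haldane")
    if min(margins) == 0:
        res.statistic = np.nan
        res.p_value = 1.0
        res.flags.append("zero_margin")
        return res
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    res.statistic = float(chi2)
    res.p_value = float(stats.chi2.sf(chi2, df=1))
    if a + b > 0:
        res.maf_case = a / (a + b)
    if c + d > 0:
        res.maf_control = c / (c + d)
    res.maf_overall = (a + c) / n
    return res


def carrier_proportion(genotypes) -> float:
    """Fraction of individuals carrying at least one minor allele."""
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise DataError("all genotypes missing")
    return float((g >= 1).mean())


def maf(genotypes) -> float:
    """Minor allele frequency ``min(f, 1-f)`` with ``f = sum(g)/(2n)``."""
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise DataError("all genotypes missing")
    f = g.sum() / (2 * g.size)
    return float(min(f, 1.0 - f))


def logistic_assoc(genotypes, status, covariates=None) -> SnpAssocResult:
    """Additive logistic regression of case status on dosage.

    Maximum likelihood by Newton/IRLS (log-likelihood tolerance 1e-8,
    at most 100 iterations).  The reported P is the Wald test on the dosage
    slope and OR = exp(slope).  |slope| > 10 flags near-separation;
    non-convergence returns a flagged result with P missing rather than a
    silently unreliable number.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(status, dtype=float)
    if covariates is not None:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != g.size:
            Z = Z.T
        keep = ~(np.isnan(g) | np.isnan(y) | np.isnan(Z).any(axis=1))
        g, y, Z = g[keep], y[keep], Z[keep]
    else:
        keep = ~(np.isnan(g) | np.isnan(y))
        g, y = g[keep], y[keep]
        Z = None

    res = SnpAssocResult(test="logistic", n_case=int((y == 1).sum()), n_control=int((y == 0).sum()))
    if res.n_case == 0 or res.n_control == 0:
        raise DataError("need at least one case and one control")
    res.maf_case = maf(g[y == 1]) if res.n_case else np.nan
    res.maf_control = maf(g[y == 0]) if res.n_control else np.nan
    res.maf_overall = maf(g)

    X = np.column_stack([np.ones_like(g), g] if Z is None else [np.ones_like(g), g, Z])
    if np.ptp(g) == 0:
        res.flags.append("monomorphic")
        res.p_value = np.nan
        return res
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0, warn_convergence=False)
        converged = bool(fit.mle_retvals.get("converged", False))
        slope = float(fit.params[1])
        se = float(fit.bse[1])
    except Exception:
        converged, slope, se = False, np.nan, np.nan

    if not converged or not np.isfinite(slope) or not np.isfinite(se) or se == 0:
        res.flags.append("nonconverged")
        res.p_value = np.nan
        res.statistic = np.nan
        res.odds_ratio = np.nan
        return res
    if abs(slope) > 10:
        res.flags.append("near_separation")
        res.p_value = np.nan
        res.statistic = np.nan
        res.odds_ratio = np.nan
        return res
    z = slope / se
    res.statistic = float(z * z)
    res.p_value = float(stats.chi2.sf(z * z, df=1))
    res.odds_ratio = float(np.exp(slope))
    return res


def allelic_scan(dosage: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Vectorised allelic chi-square P values for a dosage matrix.

    ``dosage`` is (n_samples, n_snps) with NaN for missing; returns an
    array of P values (NaN-safe, P=1 where a margin is empty).  Used by the
    genome scan and the calibration studies where per-SNP object overhead
    matters.
    """
    y = np.asarray(status, dtype=float)
    case = y == 1
    ctrl = y == 0
    obs = ~np.isnan(dosage)
    d0 = np.where(obs, dosage, 0.0)
    a = d0[case].sum(axis=0)
    c = d0[ctrl].sum(axis=0)
    n_case = obs[case].sum(axis=0)
    n_ctrl = obs[ctrl].sum(axis=0)
    b = 2 * n_case - a
    d = 2 * n_ctrl - c
    n = a + b + c + d
    m1, m2, m3, m4 = a + b, c + d, a + c, b + d
    denom = m1 * m2 * m3 * m4
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
    p = np.where(np.isnan(chi2), 1.0, stats.chi2.sf(np.nan_to_num(chi2), df=1))
    return p
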