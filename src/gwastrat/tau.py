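"""Generalized Kendall's tau association between one SNP and a
multivariate (binary) trait vector.

The statistic is the U-vector

    U = C(n,2)^{-1} * sum_{i<j} (Y_i - Y_j)(g_i - g_j),

computed via the algebraic identity
``sum_{i<j}(Y_i - Y_j)(g_i - g_j) = n * sum_i Y_i g_i - (sum Y)(sum g)``
in O(np).  Conditional on the observed phenotypes, the null distribution of
U is that induced by uniformly random permutation of the genotype vector;
its mean is 0 and its covariance has the closed form

    Cov(U) = n^2 / ( (n-1) * C(n,2)^2 ) * S_Y * s_g,

with S_Y the centered trait cross-product matrix and s_g the centered
genotype sum of squares (classical permutation moments of a linear
statistic).  The test statistic is the quadratic form U' Sigma^+ U with
rank-based degrees of freedom, referred to chi-square (or to the
permutation distribution).

The covariate-adjusted variant weights subject pairs by a Gaussian kernel
on standardized covariate distance (Silverman's rule bandwidth), so pairs
with similar covariates dominate; inference is by permutation of g with the
weights held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import DataError


@dataclass
class TauResult:
    U: np.ndarray
    n: int
    sigma: np.ndarray
    statistic: float
    df: int
    p_value: float
    adjusted: bool = False
    n_permutations: int = 0
    flags: tuple = ()


def _check_inputs(Y, g):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    g = np.asarray(g, dtype=float)
    if g.ndim != 1 or Y.shape[0] != g.size:
        raise DataError("Y must be n x p and g length n")
    if np.isnan(Y).any() or np.isnan(g).any():
        raise DataError("missing values must be removed before the tau test")
    if g.size < 2:
        raise DataError("need at least two subjects")
    return Y, g


def u_statistic(Y, g) -> np.ndarray:
    """Generalized Kendall's tau U-vector (length p)."""
    Y, g = _check_inputs(Y, g)
    n = g.size
    raw = n * (Y.T @ g) - Y.sum(axis=0) * g.sum()
    return raw / (n * (n - 1) / 2.0)


def tau_null_covariance(Y, g) -> np.ndarray:
    """Exact covariance of U under random permutation of ``g`` given ``Y``."""
    Y, g = _check_inputs(Y, g)
    n = g.size
    Yc = Y - Y.mean(axis=0)
    S_Y = Yc.T @ Yc
    s_g = float(((g - g.mean()) ** 2).sum())
    pairs = n * (n - 1) / 2.0
    return (n * n) / ((n - 1) * pairs * pairs) * S_Y * s_g


def _quadratic_form(U, sigma, rel_cutoff: float = 1e-10):
    """(statistic, df) via eigenvalue-cutoff pseudoinverse of sigma."""
    w, V = np.linalg.eigh(sigma)
    lam_max = w.max() if w.size else 0.0
    if lam_max <= 0:
        return 0.0, 0
    keep = w > rel_cutoff * lam_max
    df = int(keep.sum())
    if df == 0:
        return 0.0, 0
    Ut = V.T @ U
    stat = float(np.sum(Ut[keep] ** 2 / w[keep]))
    return max(stat, 0.0), df


def tau_test(Y, g, mode: str = "analytic", n_perm: int = 10000, seed=None) -> TauResult:
    """Test association between the trait matrix and one SNP.

    ``mode='analytic'`` refers U' Sigma^+ U to chi-square with df = rank(Sigma);
    ``mode='permutation'`` uses the permutation distribution of the same
    quadratic form (Sigma is permutation-invariant, so the pseudoinverse is
    computed once), with P = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if mode not in ("analytic", "permutation"):
        raise ValueError("mode must be 'analytic' or 'permutation'")
    Y, g = _check_inputs(Y, g)
    n = g.size
    U = u_statistic(Y, g)
    sigma = tau_null_covariance(Y, g)
    stat, df = _quadratic_form(U, sigma)
    flags = []
    if df == 0:
        return TauResult(U, n, sigma, 0.0, 0, 1.0, flags=("zero_rank",))
    if mode == "analytic":
        p = float(stats.chi2.sf(stat, df=df))
        return TauResult(U, n, sigma, stat, df, p)
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(sigma)
    keep = w > 1e-10 * w.max()
    sums_y = Y.sum(axis=0)
    pairs = n * (n - 1) / 2.0
    count = 0
    for _ in range(n_perm):
        gp = rng.permutation(g)
        Up = (n * (Y.T @ gp) - sums_y * gp.sum()) / pairs
        Ut = V.T @ Up
        sp = np.sum(Ut[keep] ** 2 / w[keep])
        if sp >= stat - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return TauResult(U, n, sigma, stat, df, float(p), n_permutations=n_perm)


def silverman_bandwidth(z: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for one standardized covariate."""
    n = z.size
    sd = z.std(ddof=1)
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale == 0:
        return 0.0
    return 0.9 * scale * n ** (-0.2)


def _kernel_weights(Z: np.ndarray) -> np.ndarray:
    """Symmetric Gaussian-kernel pair weights on standardized covariates.

    Covariates with zero spread contribute nothing to the distance (all
    pairs equal), so constant covariates reduce the weighted statistic to
    the unweighted one.
    """
    n, q = Z.shape
    d2 = np.zeros((n, n))
    for k in range(q):
        z = Z[:, k]
        sd = z.std(ddof=1) if n > 1 else 0.0
        if sd == 0:
            continue
        zs = (z - z.mean()) / sd
        h = silverman_bandwidth(zs)
        if h == 0:
            continue
        diff = (zs[:, None] - zs[None, :]) / h
        d2 += diff * diff
    W = np.exp(-0.5 * d2)
    np.fill_diagonal(W, 0.0)
    return W


def tau_test_adjusted(Y, g, Z, n_perm: int = 2000, seed=None) -> TauResult:
    """Covariate-weighted generalized tau test.

    ``U_w = (sum_{i<j} w_ij)^{-1} sum_{i<j} w_ij (Y_i - Y_j)(g_i - g_j)``
    with Gaussian-kernel pair weights on standardized covariate distance.
    The null covariance of U_w and the P value both come from permutation
    of g with the weights fixed; the statistic is the quadratic form in the
    permutation covariance.
    """
    Y, g = _check_inputs(Y, g)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != g.size:
        raise DataError("covariate rows must match n")
    if np.isnan(Z).any():
        raise DataError("covariates must be complete")
    n = g.size
    W = _kernel_weights(Z)
    total_w = W.sum() / 2.0
    if total_w <= 0:
        raise DataError("total pair weight is zero")
    r = W.sum(axis=1)  # row sums

    YtW = Y.T @ W  # p x n, fixed across permutations
    rY = Y * r[:, None]  # n x p

    def u_w(gv: np.ndarray) -> np.ndarray:
        # sum_{i<j} w_ij (Y_i - Y_j)(g_i - g_j) = sum_i r_i Y_i g_i - Y' W g
        return (rY.T @ gv - YtW @ gv) / total_w

    U = u_w(g)
    rng = np.random.default_rng(seed)
    perm_U = np.empty((n_perm, Y.shape[1]))
    for b in range(n_perm):
        perm_U[b] = u_w(rng.permutation(g))
    sigma = np.cov(perm_U, rowvar=False)
    sigma = np.atleast_2d(sigma)
    stat, df = _quadratic_form(U, sigma)
    if df == 0:
        return TauResult(U, n, sigma, 0.0, 0, 1.0, adjusted=True, flags=("zero_rank",))
    w_eig, V = np.linalg.eigh(sigma)
    keep = w_eig > 1e-10 * w_eig.max()
    Ut = (perm_U @ V)[:, keep]
    perm_stats = np.sum(Ut * Ut / w_eig[keep], axis=1)
    count = int(np.sum(perm_stats >= stat - 1e-12))
    p = (1 + count) / (1 + n_perm)
    return TauResult(U, n, sigma, stat, df, float(p), adjusted=True, n_permutations=n_perm)
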