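"""Phylogenetic signal of a continuous trait: Blomberg's K and Pagel's lambda.

Blomberg's K compares the ratio of among-species variance to
phylogenetically corrected variance against its Brownian-motion
expectation; K = 1 under pure Brownian evolution, K < 1 indicates less
resemblance among relatives than Brownian motion predicts, K > 1 more.
Significance comes from permuting trait values across tips.

Pagel's lambda rescales the off-diagonal entries of the phylogenetic
covariance matrix by a factor in [0, 1] and is estimated by maximum
likelihood; lambda = 0 reduces to a star phylogeny (no signal), lambda = 1
to Brownian motion.  The reported P-value is a likelihood-ratio test of
lambda-hat against lambda = 0 on one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .treeio import DatedTree, lambda_transform

__all__ = [
    "SignalResult",
    "align_trait",
    "phylo_mean",
    "blomberg_K",
    "k_permutation_test",
    "bm_loglik",
    "pagel_lambda",
]


@dataclass(frozen=True)
class SignalResult:
    """One signal statistic for one trait on one tree."""

    statistic_name: str  # "K" or "lambda"
    estimate: float
    p_value: float
    n_species: int
    n_replicates: Optional[int] = None  # permutation count (K only)
    loglik_est: Optional[float] = None  # lambda only
    loglik_null: Optional[float] = None
    sigma2_hat: Optional[float] = None
    phylo_mean_hat: Optional[float] = None

    def __post_init__(self) -> None:
        if self.loglik_est is not None and self.loglik_null is not None:
            if self.loglik_est < self.loglik_null - 1e-8:
                raise ValueError("fitted log-likelihood below the null — optimizer failure")


def align_trait(
    tree: DatedTree, x: pd.Series, min_species: int = 3
) -> tuple[DatedTree, np.ndarray]:
    """Match a species-indexed trait to a tree.

    Tips absent from the trait are pruned; trait entries absent from the
    tree are dropped.  Returns the (possibly pruned) tree and the trait as
    an array ordered by ``tree.labels``.  Matching is exact and
    case-sensitive.
    """
    x = x.dropna()
    if x.index.has_duplicates:
        dupes = sorted(x.index[x.index.duplicated()].unique())
        raise ValueError(f"duplicate species in trait vector: {dupes}")
    common = [lab for lab in tree.labels if lab in x.index]
    if len(common) < min_species:
        raise ValueError(
            f"only {len(common)} species shared between tree and trait; "
            f"need >= {min_species}"
        )
    if len(common) < tree.n_tips:
        tree = tree.prune_to(common)
    vals = x.loc[list(tree.labels)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite trait values after matching")
    return tree, vals


def _cho(C: np.ndarray):
    try:
        return linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "phylogenetic covariance matrix is singular; check for duplicate "
            "tips or zero-length terminal branch pairs (a diagonal jitter of "
            "~1e-10*root_age can be applied upstream if intended)"
        ) from exc


def phylo_mean(x: np.ndarray, C: np.ndarray) -> float:
    """GLS estimate of the root state: (1'C^-1 1)^-1 1'C^-1 x."""
    x = np.asarray(x, dtype=float)
    cf = _cho(C)
    ones = np.ones(len(x))
    Ci1 = linalg.cho_solve(cf, ones)
    return float(Ci1 @ x / (Ci1 @ ones))


def _k_statistic(x: np.ndarray, cf, Ci1: np.ndarray, expected_ratio: float) -> float:
    # MSE0/MSE for the observed data over the BM expectation of that ratio
    n = len(x)
    ahat = (Ci1 @ x) / (Ci1 @ np.ones(n))
    r = x - ahat
    mse0 = r @ r / (n - 1)
    mse = r @ linalg.cho_solve(cf, r) / (n - 1)
    return float((mse0 / mse) / expected_ratio)


def _k_setup(tree: DatedTree, x: np.ndarray):
    n = len(x)
    if n < 3:
        raise ValueError("Blomberg's K needs at least 3 species")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; K is undefined")
    C = tree.vcv()
    cf = _cho(C)
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cf, ones)
    expected_ratio = (np.trace(C) - n / (ones @ Ci1)) / (n - 1)
    return C, cf, Ci1, expected_ratio


def blomberg_K(tree: DatedTree, x: pd.Series | np.ndarray) -> float:
    """Blomberg's K of a trait on a dated tree (K = 1 under Brownian motion)."""
    if isinstance(x, pd.Series):
        tree, x = align_trait(tree, x)
    x = np.asarray(x, dtype=float)
    _, cf, Ci1, expected_ratio = _k_setup(tree, x)
    return _k_statistic(x, cf, Ci1, expected_ratio)


def k_permutation_test(
    tree: DatedTree,
    x: pd.Series | np.ndarray,
    n_replicates: int = 9999,
    seed=None,
) -> SignalResult:
    """Permutation test for K: shuffle trait values across tips.

    One-sided (signal is large): P = (1 + #{K_perm >= K_obs}) / (1 + B)
    with add-one smoothing, so P is never below 1/(B+1).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if isinstance(x, pd.Series):
        tree, x = align_trait(tree, x)
    x = np.asarray(x, dtype=float)
    C, cf, Ci1, expected_ratio = _k_setup(tree, x)
    k_obs = _k_statistic(x, cf, Ci1, expected_ratio)

    rng = np.random.default_rng(seed)
    n = len(x)
    # vectorized: K depends on x only through MSE0 and MSE, both quadratic;
    # the observed vector rides along as column 0 so it goes through the
    # identical floating-point path as the permutations
    perms = rng.permuted(np.tile(x, (n_replicates, 1)), axis=1).T  # n x B
    cols = np.column_stack([x, perms])
    ones = np.ones(n)
    ahat = (Ci1 @ cols) / (Ci1 @ ones)
    R = cols - ahat  # residuals per column
    mse0 = np.einsum("ij,ij->j", R, R)
    CiR = linalg.cho_solve(cf, R)
    mse = np.einsum("ij,ij->j", R, CiR)
    k_all = (mse0 / mse) / expected_ratio
    p = (1 + int(np.sum(k_all[1:] >= k_all[0]))) / (1 + n_replicates)
    ahat_obs = phylo_mean(x, C)
    return SignalResult(
        statistic_name="K",
        estimate=k_obs,
        p_value=p,
        n_species=n,
        n_replicates=n_replicates,
        phylo_mean_hat=ahat_obs,
    )


def bm_loglik(C: np.ndarray, x: np.ndarray, lam: float) -> tuple[float, float, float]:
    """Profile log-likelihood of the lambda model at a given lambda.

    The trait is multivariate normal with mean ``a*1`` and covariance
    ``sigma2 * C_lambda``.  Profiling out ``a`` (GLS) and ``sigma2`` (its
    ML estimate) gives
    ``loglik = -1/2 [n ln(2 pi sigma2_hat) + ln det C_lambda + n]``.
    Returns ``(loglik, sigma2_hat, mean_hat)``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    Cl = lambda_transform(C, lam)
    cf = _cho(Cl)
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cf, ones)
    ahat = float(Ci1 @ x / (Ci1 @ ones))
    r = x - ahat
    sigma2 = float(r @ linalg.cho_solve(cf, r) / n)
    if sigma2 <= 0:
        raise ValueError("degenerate trait: ML sigma2 is zero")
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(loglik), sigma2, ahat


def pagel_lambda(tree: DatedTree, x: pd.Series | np.ndarray) -> SignalResult:
    """ML estimate of Pagel's lambda on [0, 1] with a LR test against 0.

    The likelihood is maximized by bounded scalar optimization (tolerance
    1e-8) and checked against both boundaries, which are legitimate
    estimates.  P comes from 2*(logL(lambda_hat) - logL(0)) against a
    chi-square with 1 df; near the boundary this is conservative.
    """
    if isinstance(x, pd.Series):
        tree, x = align_trait(tree, x)
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Pagel's lambda needs at least 3 species")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant; lambda is undefined")
    C = tree.vcv()

    def nll(lam: float) -> float:
        return -bm_loglik(C, x, lam)[0]

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(f"lambda optimizer failed: {res.message}")
    candidates = [(float(res.x), float(res.fun)), (0.0, nll(0.0)), (1.0, nll(1.0))]
    lam_hat, neg_ll = min(candidates, key=lambda t: t[1])
    ll_hat, sigma2_hat, ahat = bm_loglik(C, x, lam_hat)
    ll0 = -candidates[1][1]
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return SignalResult(
        statistic_name="lambda",
        estimate=lam_hat,
        p_value=p,
        n_species=len(x),
        loglik_est=ll_hat,
        loglik_null=ll0,
        sigma2_hat=sigma2_hat,
        phylo_mean_hat=ahat,
    )
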