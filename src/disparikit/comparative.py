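"""Ecology-morphology association machinery.

Pagel's lambda phylogenetic signal, phylogenetic PCA, PGLS regression with ML
lambda, simulation-based phylogenetic ANOVA, and the Paired Difference Index
(PDI) of ecological specialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ._gauss import profiled_gaussian
from .tree import (
    Phylogeny,
    phylo_covariance,
    trait_matrix,
    trait_vector,
)

__all__ = [
    "PhyloSignalResult",
    "PglsResult",
    "PhyloAnovaResult",
    "pagel_lambda",
    "phylo_pca",
    "pgls",
    "phylo_anova",
    "pdi",
]


# ----------------------------------------------------------- lambda machinery
def _lambda_matrix(C: np.ndarray, lam: float) -> np.ndarray:
    M = C * lam
    np.fill_diagonal(M, np.diag(C))
    return M


def lambda_max_pd(C: np.ndarray, upper: float = 2.0) -> float:
    """Largest lambda keeping the transformed covariance positive definite."""
    def pd_ok(lam):
        try:
            linalg.cholesky(_lambda_matrix(C, lam), lower=True)
            return True
        except linalg.LinAlgError:
            return False

    if not pd_ok(1.0):
        return 1.0
    lo, hi = 1.0, upper
    if pd_ok(hi):
        return hi
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if pd_ok(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _profile_lambda_loglik(C: np.ndarray, W: np.ndarray, x: np.ndarray):
    def loglik(lam: float) -> float:
        try:
            return profiled_gaussian(_lambda_matrix(C, lam), W, x)[0]
        except linalg.LinAlgError:
            return -np.inf
    return loglik


def _maximize_lambda(loglik, lam_max: float, n_grid: int = 21) -> float:
    """Coarse grid then bounded refinement; ties broken toward smaller lambda."""
    grid = np.linspace(0.0, lam_max, n_grid)
    vals = np.array([loglik(g) for g in grid])
    i = int(np.argmax(vals))  # argmax takes the first (smallest lambda) on ties
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if hi <= lo:
        return float(grid[i])
    res = optimize.minimize_scalar(lambda l: -loglik(l), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    best = float(res.x) if -res.fun >= vals[i] else float(grid[i])
    return best


@dataclass
class PhyloSignalResult:
    lambda_hat: float
    loglik: float
    loglik_lambda0: float
    p_value: float
    lambda_max: float


def pagel_lambda(tree: Phylogeny, trait) -> PhyloSignalResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test against 0.

    lambda multiplies the off-diagonal phylogenetic covariances: 0 means no
    phylogenetic signal (star phylogeny), 1 the full Brownian expectation.
    """
    x = trait_vector(tree, trait)
    if tree.n_tips < 4:
        raise ValueError("Pagel's lambda needs at least 4 species")
    C = phylo_covariance(tree).matrix
    W = np.ones((len(x), 1))
    loglik = _profile_lambda_loglik(C, W, x)
    lam_max = lambda_max_pd(C)
    lam_hat = _maximize_lambda(loglik, lam_max)
    l_hat, l_0 = loglik(lam_hat), loglik(0.0)
    if l_0 > l_hat:  # boundary is the optimum
        lam_hat, l_hat = 0.0, l_0
    lr = max(2.0 * (l_hat - l_0), 0.0)
    return PhyloSignalResult(lam_hat, l_hat, l_0, float(stats.chi2.sf(lr, 1)),
                             lam_max)


# -------------------------------------------------------------- phylogenetic PCA
def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    vecs = vecs.copy()
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


@dataclass
class PhyloPcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_prop: np.ndarray
    eigenvalues: np.ndarray
    gls_mean: np.ndarray


def phylo_pca(tree: Phylogeny, traits: pd.DataFrame) -> PhyloPcaResult:
    """Phylogenetic PCA: eigendecomposition of the evolutionary rate matrix.

    R = (X - mu)' C^-1 (X - mu) / (n - 1) with mu the GLS (phylogenetic) mean;
    scores are (X - mu) projected on R's eigenvectors. On a star tree this
    reduces to ordinary covariance PCA of centered data.
    """
    X = trait_matrix(tree, traits)
    n, k = X.shape
    if k < 2:
        raise ValueError("phylogenetic PCA needs at least 2 traits")
    C = phylo_covariance(tree).matrix
    L = linalg.cholesky(C, lower=True)
    one = linalg.solve_triangular(L, np.ones(n), lower=True)
    Xt = linalg.solve_triangular(L, X, lower=True)
    mu = (one @ Xt) / (one @ one)
    Xc = X - mu
    Xct = Xt - np.outer(one, mu)
    R = Xct.T @ Xct / (n - 1)
    eig, vec = np.linalg.eigh(R)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], _fix_signs(vec[:, order])
    cols = [f"pPC{i + 1}" for i in range(k)]
    names = list(traits.columns) if isinstance(traits, pd.DataFrame) else list(range(k))
    scores = pd.DataFrame(Xc @ vec, index=tree.tip_labels, columns=cols)
    loadings = pd.DataFrame(vec, index=names, columns=cols)
    eig = np.clip(eig, 0.0, None)
    return PhyloPcaResult(scores, loadings, eig / eig.sum(), eig, mu)


# ------------------------------------------------------------------------ PGLS
@dataclass
class PglsResult:
    coefficients: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    lambda_hat: float
    lambda_estimated: bool
    sigma2: float
    loglik: float
    n: int
    df_resid: int


def pgls(tree: Phylogeny, y, X=None, estimate_lambda: bool = True,
         fixed_lambda: float = 1.0) -> PglsResult:
    """Phylogenetic GLS regression with lambda-transformed residual covariance.

    ``X`` is a species-indexed DataFrame of predictors (an intercept is added);
    ``X=None`` fits the intercept-only model (the phylogenetic mean). With
    ``estimate_lambda`` the residual lambda is estimated by ML; otherwise
    ``fixed_lambda`` is used (0 recovers OLS, 1 standard BM GLS). t tests use
    sigma2 = RSS_gls/(n-p) on n-p degrees of freedom.
    """
    yv = trait_vector(tree, y)
    n = len(yv)
    names = ["intercept"]
    W = np.ones((n, 1))
    if X is not None:
        if isinstance(X, pd.Series):
            X = X.to_frame()
        Xm = trait_matrix(tree, X)
        names += [str(c) for c in (X.columns if isinstance(X, pd.DataFrame)
                                   else range(Xm.shape[1]))]
        W = np.hstack([W, Xm])
    p = W.shape[1]
    if n <= p + 1:
        raise ValueError("too few species for the design")
    if np.linalg.matrix_rank(W) < p:
        raise ValueError(f"rank-deficient design; columns: {names}")
    C = phylo_covariance(tree).matrix
    if estimate_lambda:
        loglik = _profile_lambda_loglik(C, W, yv)
        lam = _maximize_lambda(loglik, lambda_max_pd(C))
    else:
        lam = float(fixed_lambda)
    V0 = _lambda_matrix(C, lam)
    logl, beta, _, extras = profiled_gaussian(V0, W, yv)
    sigma2 = extras["q"] / (n - p)
    cov_beta = sigma2 * linalg.inv(extras["XtX"])
    se = np.sqrt(np.diag(cov_beta))
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - p)
    return PglsResult(
        coefficients=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        t_values=pd.Series(tval, index=names),
        p_values=pd.Series(pval, index=names),
        lambda_hat=lam, lambda_estimated=bool(estimate_lambda),
        sigma2=float(sigma2), loglik=float(logl), n=n, df_resid=n - p,
    )


# ------------------------------------------------------------ phylogenetic ANOVA
@dataclass
class PhyloAnovaResult:
    f_observed: float
    p_standard: float
    p_phylo: float
    n_sim: int
    group_means: pd.Series


def _anova_f(X: np.ndarray, G: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """One-way F for each column of X given group indicator matrix G."""
    n, k = X.shape[0], G.shape[1]
    means = (G.T @ X) / sizes[:, None]
    grand = X.mean(axis=0)
    ssb = (sizes[:, None] * (means - grand) ** 2).sum(axis=0)
    sst = ((X - grand) ** 2).sum(axis=0)
    ssw = sst - ssb
    return (ssb / (k - 1)) / (ssw / (n - k))


def phylo_anova(tree: Phylogeny, trait, groups, n_sim: int = 10000,
                seed: int | None = 0,
                rng: np.random.Generator | None = None) -> PhyloAnovaResult:
    """Simulation-based phylogenetic ANOVA.

    The observed one-way F statistic is compared with a null distribution of F
    from Brownian-motion simulations on the tree (rate estimated from the data
    by ML), giving phylo-p = (#{F_sim >= F_obs} + 1)/(n_sim + 1).
    """
    x = trait_vector(tree, trait)
    if isinstance(groups, pd.Series):
        g = groups.loc[tree.tip_labels].to_numpy()
    else:
        g = np.asarray([groups[lab] for lab in tree.tip_labels])
    levels, codes = np.unique(g, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 species")
    n, k = len(x), len(levels)
    G = np.zeros((n, k))
    G[np.arange(n), codes] = 1.0
    f_obs = float(_anova_f(x[:, None], G, sizes)[0])
    p_std = float(stats.f.sf(f_obs, k - 1, n - k))
    C = phylo_covariance(tree).matrix
    _, mu, s2, _ = profiled_gaussian(C, np.ones((n, 1)), x)
    if rng is None:
        rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C)
    sims = mu[0] + np.sqrt(s2) * (L @ rng.standard_normal((n, n_sim)))
    f_sim = _anova_f(sims, G, sizes)
    p_phylo = (int((f_sim >= f_obs).sum()) + 1) / (n_sim + 1)
    means = pd.Series((G.T @ x) / sizes, index=levels)
    return PhyloAnovaResult(f_obs, p_std, p_phylo, n_sim, means)


# ------------------------------------------------------------------------- PDI
def pdi(matrix: pd.DataFrame) -> pd.Series:
    """Paired Difference Index of ecological specialization per species.

    Scores are sorted descending and normalized by the row maximum;
    PDI = sum_{i=2..H} (P1 - Pi) / (H - 1), giving 1 for a complete
    specialist (one nonzero habitat) and 0 for a complete generalist
    (uniform scores). Invariant to positive rescaling of a row.
    """
    M = matrix.to_numpy(dtype=float)
    if M.shape[1] < 2:
        raise ValueError("PDI needs at least 2 habitats")
    if np.any(M < 0):
        raise ValueError("habitat scores must be nonnegative")
    row_max = M.max(axis=1)
    zero_rows = row_max == 0
    if zero_rows.any():
        bad = list(matrix.index[zero_rows])
        raise ValueError(f"all-zero habitat rows (association undefined): {bad}")
    P = np.sort(M / row_max[:, None], axis=1)[:, ::-1]
    H = M.shape[1]
    out = (P[:, [0]] - P[:, 1:]).sum(axis=1) / (H - 1)
    return pd.Series(out, index=matrix.index, name="pdi")
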