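"""Profiled multivariate-Gaussian likelihood used by every GLS-based method.

All trait-evolution models here have the form x ~ N(W beta, s * V0) with V0 a
structure matrix (from the tree and the model's nonlinear parameters), W a
known design, and (beta, s) profiled analytically at the ML solution.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

LOG2PI = np.log(2.0 * np.pi)


def chol_logdet(V0: np.ndarray):
    """Cholesky factor and log-determinant; raises LinAlgError if not PD."""
    L = linalg.cholesky(V0, lower=True)
    return L, 2.0 * np.log(np.diag(L)).sum()


def profiled_gaussian(V0: np.ndarray, W: np.ndarray, x: np.ndarray):
    """ML profile of x ~ N(W beta, s V0) over beta (GLS) and the scale s.

    Returns (logL, beta, s, extras) where extras carries the Cholesky factor
    and the GLS normal matrix for standard-error computation. Raises
    numpy/scipy LinAlgError when V0 is not positive definite.
    """
    n = len(x)
    L, logdet = chol_logdet(V0)
    Wt = linalg.solve_triangular(L, W, lower=True)
    xt = linalg.solve_triangular(L, x, lower=True)
    XtX = Wt.T @ Wt
    # lstsq keeps the profile well-defined when a design column degenerates
    # (e.g. a regime's selection exposure vanishing as alpha -> 0); the rcond
    # cutoff returns the min-norm coefficient on such directions instead of
    # an unidentifiable O(1/eps) optimum
    beta = np.linalg.lstsq(Wt, xt, rcond=1e-8)[0]
    r = xt - Wt @ beta
    q = float(r @ r)
    s = q / n
    if s <= 0:
        # degenerate (zero residual variance); likelihood unbounded
        return np.inf, beta, 0.0, {"L": L, "XtX": XtX, "q": q, "logdet": logdet}
    logl = -0.5 * (n * LOG2PI + n * np.log(s) + logdet + n)
    return logl, beta, s, {"L": L, "XtX": XtX, "q": q, "logdet": logdet}


def gaussian_loglik(V: np.ndarray, mu: np.ndarray, x: np.ndarray) -> float:
    """Plain MVN log density at fixed mean and covariance."""
    n = len(x)
    L, logdet = chol_logdet(V)
    r = linalg.solve_triangular(L, x - mu, lower=True)
    return float(-0.5 * (n * LOG2PI + logdet + r @ r))


def gls_mean(V: np.ndarray, x: np.ndarray) -> float:
    """Phylogenetic (GLS) mean: intercept-only GLS under covariance V."""
    L, _ = chol_logdet(V)
    one = linalg.solve_triangular(L, np.ones_like(x), lower=True)
    xt = linalg.solve_triangular(L, x, lower=True)
    return float(one @ xt / (one @ one))
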