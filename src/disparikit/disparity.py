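"""Disparity-through-time curves, the MDI statistic, the node-height test,
and phylomorphospace coordinates.

Disparity is the average pairwise squared Euclidean distance among species.
The DTT curve tracks, at each internal-node time, the mean relative disparity
of the subclades whose stem lineage crosses that time; the curve is compared
with Brownian-motion nulls simulated at the rate (matrix) estimated from the
data, and the MDI is the signed area between the observed and null-mean
curves over relative time [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tree import (
    Phylogeny,
    ancestral_states_ml,
    independent_contrasts,
    phylo_covariance,
    trait_matrix,
)

__all__ = [
    "trait_disparity",
    "DttResult",
    "dtt",
    "mdi",
    "NodeHeightTestResult",
    "node_height_test",
    "phylomorphospace",
]


def trait_disparity(values) -> float:
    """Average squared Euclidean distance among all unordered pairs of rows."""
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise ValueError("empty set has no disparity")
    n = X.shape[0]
    if n == 1:
        return 0.0
    # center first: the identity sum_{i<j}||xi-xj||^2 = n * sum||xi - mean||^2
    # is then exact for identical rows (no catastrophic cancellation)
    Xc = X - X.mean(axis=0)
    return float(2.0 * (Xc ** 2).sum() / (n - 1))


def _subclade_membership(tree: Phylogeny):
    """For each internal-node time, the tips of each lineage crossing it.

    Returns (times, memberships) where times[0] = 0 (the root) pairs with the
    whole clade and each later time t pairs with a boolean matrix
    (lineages x tips) of the subclades present just before t.
    """
    h = tree.node_heights
    internal = np.asarray([n for n in range(tree.n_nodes) if not tree.is_tip(n)])
    times = np.sort(h[internal])
    clades = tree.clade_tips
    child_h = h
    parent_h = np.where(tree.parent >= 0, h[tree.parent], 0.0)
    memberships = []
    nodes = np.arange(tree.n_nodes)
    non_root = nodes != tree.root
    for t in times:
        if t <= 0:
            M = np.ones((1, tree.n_tips), dtype=bool)
        else:
            crossing = nodes[non_root & (parent_h < t) & (child_h >= t)]
            M = np.zeros((len(crossing), tree.n_tips), dtype=bool)
            for i, c in enumerate(crossing):
                M[i, clades[c]] = True
        memberships.append(M)
    return times, memberships


def _dtt_curve(memberships, X: np.ndarray) -> np.ndarray:
    """Mean relative subclade disparity at each stored time.

    ``X`` has shape (n_tips, k, n_sets); the curve is computed for every set
    simultaneously. The total-clade disparity normalizes each set.
    """
    n_tips, k, m = X.shape
    S1 = X  # per-tip values
    sq = (X ** 2).sum(axis=1)  # (tips, sets)
    total = None
    out = np.empty((len(memberships), m))
    for j, M in enumerate(memberships):
        cnt = M.sum(axis=1).astype(float)  # (lineages,)
        s1 = np.einsum("lt,tks->lks", M.astype(float), X)
        s2 = M.astype(float) @ sq  # (lineages, sets)
        with np.errstate(invalid="ignore", divide="ignore"):
            disp = 2.0 * (cnt[:, None] * s2 - (s1 ** 2).sum(axis=1)) / (
                cnt * (cnt - 1.0))[:, None]
        disp[cnt <= 1] = 0.0
        if j == 0:
            total = disp[0]  # whole clade
        with np.errstate(invalid="ignore", divide="ignore"):
            out[j] = disp.mean(axis=0) / total
    return out


@dataclass
class DttResult:
    relative_times: np.ndarray
    observed_curve: np.ndarray
    null_mean_curve: np.ndarray
    null_low: np.ndarray
    null_high: np.ndarray
    mdi: float
    p_mdi: float
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "relative_time": self.relative_times,
            "observed": self.observed_curve,
            "null_mean": self.null_mean_curve,
            "null_low95": self.null_low,
            "null_high95": self.null_high,
        })


def mdi(observed_curve, null_mean_curve, relative_times) -> float:
    """Signed area (observed - null) by the trapezoid rule over [0, 1].

    Positive values mean disparity concentrated within subclades.
    """
    obs = np.asarray(observed_curve, dtype=float)
    nul = np.asarray(null_mean_curve, dtype=float)
    t = np.asarray(relative_times, dtype=float)
    if obs.shape != t.shape or nul.shape != t.shape:
        raise ValueError("curves and time grid have mismatched lengths")
    return float(np.trapezoid(obs - nul, t))


def dtt(tree: Phylogeny, traits, n_sim: int = 1000, seed: int | None = 0,
        rng: np.random.Generator | None = None) -> DttResult:
    """Disparity-through-time with a BM null envelope and the MDI statistic.

    The observed curve starts at exactly 1 (the whole clade at the root) and
    is closed with a 0 at relative time 1 (every subclade a single tip). The
    null is ``n_sim`` BM simulations at the ML rate (matrix) estimated from
    the data; p_mdi is one-sided (observed >= null).
    """
    if not tree.is_ultrametric(rtol=1e-6):
        raise ValueError("DTT requires an ultrametric tree")
    X = trait_matrix(tree, traits)
    n, k = X.shape
    C = phylo_covariance(tree).matrix
    T = tree.height
    times, memberships = _subclade_membership(tree)
    obs = _dtt_curve(memberships, X[:, :, None])[:, 0]
    if not np.isfinite(obs[0]):
        raise ValueError("zero total disparity; DTT undefined")
    # ML rate matrix under BM with GLS means
    L = np.linalg.cholesky(C)
    ones = np.ones((n, 1))
    mu = np.empty(k)
    R = np.empty((k, k))
    from scipy import linalg as sla
    Lt_inv_X = sla.solve_triangular(L, X, lower=True)
    Lt_inv_1 = sla.solve_triangular(L, ones, lower=True)[:, 0]
    mu = (Lt_inv_1 @ Lt_inv_X) / (Lt_inv_1 @ Lt_inv_1)
    Xc = Lt_inv_X - np.outer(Lt_inv_1, mu)
    R = Xc.T @ Xc / n
    # simulate: X_sim = mu + L Z A' with A A' = R
    eigval, eigvec = np.linalg.eigh(R)
    A = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    if rng is None:
        rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sim, n, k))
    sims = mu + np.einsum("nt,stk->snk", L, Z) @ A.T
    sims = np.moveaxis(sims, 0, 2)  # (tips, k, n_sim)
    null = _dtt_curve(memberships, sims)
    rel_t = np.concatenate([times / T, [1.0]])
    obs_full = np.concatenate([obs, [0.0]])
    null_full = np.vstack([null, np.zeros((1, n_sim))])
    null_mean = null_full.mean(axis=1)
    low = np.quantile(null_full, 0.025, axis=1)
    high = np.quantile(null_full, 0.975, axis=1)
    mdi_obs = mdi(obs_full, null_mean, rel_t)
    mdi_null = np.trapezoid(null_full - null_mean[:, None], rel_t, axis=0)
    p = (int((mdi_null >= mdi_obs).sum()) + 1) / (n_sim + 1)
    return DttResult(rel_t, obs_full, null_mean, low, high,
                     mdi_obs, p, n_sim)


@dataclass
class NodeHeightTestResult:
    slope: float
    std_error: float
    t_value: float
    p_value: float
    intercept: float
    n_contrasts: int


def node_height_test(tree: Phylogeny, trait) -> NodeHeightTestResult:
    """OLS of |standardized contrast| on node height (time since root).

    A positive slope means larger contrasts at recent nodes, i.e. an
    acceleration of trait evolution toward the present.
    """
    if tree.n_tips < 4:
        raise ValueError("node-height test needs at least 4 species")
    cs = independent_contrasts(tree, trait)
    y = np.abs(cs.contrasts)
    if np.all(y == 0):
        raise ValueError("constant trait: all contrasts are zero")
    x = cs.node_heights
    n = len(y)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("all contrasts at the same height; regression undefined")
    b = float(xc @ (y - y.mean()) / sxx)
    a = float(y.mean() - b * x.mean())
    resid = y - a - b * x
    s2 = float(resid @ resid) / (n - 2)
    se = float(np.sqrt(s2 / sxx))
    tval = b / se
    p = float(2 * stats.t.sf(abs(tval), df=n - 2))
    return NodeHeightTestResult(b, se, tval, p, a, n)


def phylomorphospace(tree: Phylogeny, scores) -> dict:
    """Tip and ML internal-node coordinates in a 2D morphospace, plus edges.

    Returns ``{"nodes": DataFrame, "edges": DataFrame}`` ready for plotting:
    internal positions are the per-axis BM ancestral-state estimates.
    """
    S = trait_matrix(tree, scores)
    if S.shape[1] != 2:
        raise ValueError("phylomorphospace needs exactly 2 score columns")
    ax1 = ancestral_states_ml(tree, S[:, 0])
    ax2 = ancestral_states_ml(tree, S[:, 1])
    labels = [tree.tip_labels[i] if tree.is_tip(i) else f"node{i}"
              for i in range(tree.n_nodes)]
    nodes = pd.DataFrame({
        "node": np.arange(tree.n_nodes),
        "label": labels,
        "is_tip": [tree.is_tip(i) for i in range(tree.n_nodes)],
        "x": ax1, "y": ax2,
        "height": tree.node_heights,
    })
    child = np.asarray([i for i in range(tree.n_nodes) if i != tree.root])
    edges = pd.DataFrame({"parent": tree.parent[child], "child": child})
    return {"nodes": nodes, "edges": edges}
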