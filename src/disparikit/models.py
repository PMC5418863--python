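"""ML fitting and AICc comparison of trait-evolution models.

Four models of continuous-trait evolution on a time-calibrated tree:

* BM   -- Brownian motion; parameters z0, sigma2 (k = 2).
* EB   -- early burst, rate sigma2 * exp(a t) with a <= 0 (k = 3).
* OU1  -- single-optimum Ornstein-Uhlenbeck with selection strength alpha,
          optimum theta, fixed root at the optimum (k = 4 as parameterized:
          z0, sigma2, alpha, theta, with z0 tied to theta).
* OUMV -- multi-regime OU over a mapped discrete regime history: per-regime
          sigma2 and theta, one global alpha, root fixed at the optimum of
          the root regime (k = 6 with two regimes).

All likelihoods are exact dense Gaussians: the covariance integrates the
(piecewise) diffusion rate along shared root-to-MRCA paths discounted by
exp(-2 alpha (T - t)), and the mean weights each optimum by the selection
exposure along the root-to-tip path. Linear parameters (optima, root state)
and one variance scale are profiled analytically, leaving at most a 2-D
numerical optimization.

Regime histories come from stochastic character mapping: an Mk rate matrix is
fitted by ML, node states are drawn from their conditional distributions, and
endpoint-conditioned substitution paths are sampled per branch (rejection
sampling with a uniformization fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from ._gauss import gaussian_loglik, profiled_gaussian
from .simulate import RegimeHistory
from .tree import Phylogeny, phylo_covariance, trait_vector

__all__ = [
    "ModelFit",
    "ModelComparison",
    "aicc",
    "fit_bm",
    "fit_eb",
    "fit_ou1",
    "fit_oumv",
    "bm_loglik",
    "eb_loglik",
    "ou1_loglik",
    "oumv_loglik",
    "fit_mk",
    "stochastic_maps",
    "compare_models",
]


# ------------------------------------------------------------------ ModelFit
@dataclass
class ModelFit:
    model: str
    sigma2: dict  # regime -> sigma2 ("" key for single-rate models)
    theta: dict | None
    alpha: float | None
    eb_rate: float | None
    z0: float
    loglik: float
    k: int
    aicc: float
    n: int
    degenerate: bool = False
    bound_hit: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def sigma2_scalar(self) -> float:
        return next(iter(self.sigma2.values()))


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _aicc_or_nan(loglik: float, k: int, n: int) -> float:
    return aicc(loglik, k, n) if n > k + 1 else np.nan


# ------------------------------------------------------------------------ BM
def fit_bm(tree: Phylogeny, trait) -> ModelFit:
    """Closed-form ML Brownian-motion fit (GLS root state, rate q/n)."""
    x = trait_vector(tree, trait)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 species")
    C = phylo_covariance(tree).matrix
    if np.ptp(x) == 0:
        return ModelFit("BM", {"": 0.0}, None, None, None, float(x[0]),
                        np.inf, 2, -np.inf, n, degenerate=True)
    logl, beta, s2, _ = profiled_gaussian(C, np.ones((n, 1)), x)
    return ModelFit("BM", {"": float(s2)}, None, None, None, float(beta[0]),
                    float(logl), 2, _aicc_or_nan(logl, 2, n), n)


def bm_loglik(tree: Phylogeny, trait, sigma2: float, z0: float) -> float:
    """BM log-likelihood at fixed parameters (for oracle checks)."""
    x = trait_vector(tree, trait)
    C = phylo_covariance(tree).matrix
    return gaussian_loglik(sigma2 * C, np.full(len(x), z0), x)


# ------------------------------------------------------------------------ EB
def _eb_structure(C: np.ndarray, a: float) -> np.ndarray:
    if a == 0:
        return C
    return np.expm1(a * C) / a


def fit_eb(tree: Phylogeny, trait, a_bounds: tuple[float, float] | None = None) -> ModelFit:
    """Early-burst fit: profile ML over the rate-decay parameter a <= 0."""
    x = trait_vector(tree, trait)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 species")
    C = phylo_covariance(tree).matrix
    T = tree.height
    if a_bounds is None:
        a_bounds = (-10.0 / T, 0.0)
    if a_bounds[0] > a_bounds[1] or a_bounds[1] > 0:
        raise ValueError("EB bounds must satisfy a_min <= a_max <= 0")
    W = np.ones((n, 1))

    def negll(a: float) -> float:
        try:
            return -profiled_gaussian(_eb_structure(C, a), W, x)[0]
        except linalg.LinAlgError:
            return np.inf

    res = optimize.minimize_scalar(negll, bounds=a_bounds, method="bounded",
                                   options={"xatol": 1e-10})
    a_hat, ll = float(res.x), -float(res.fun)
    ll0 = -negll(0.0)
    if ll0 >= ll:  # BM limit wins; snap to the nested optimum
        a_hat, ll = 0.0, ll0
    logl, beta, s2, _ = profiled_gaussian(_eb_structure(C, a_hat), W, x)
    bound = a_hat <= a_bounds[0] * 0.999
    return ModelFit("EB", {"": float(s2)}, None, None, float(a_hat),
                    float(beta[0]), float(logl), 3, _aicc_or_nan(logl, 3, n), n,
                    bound_hit=bound)


def eb_loglik(tree: Phylogeny, trait, sigma2: float, a: float, z0: float) -> float:
    x = trait_vector(tree, trait)
    C = phylo_covariance(tree).matrix
    return gaussian_loglik(sigma2 * _eb_structure(C, a), np.full(len(x), z0), x)


# ----------------------------------------------------------------------- OU1
def _ou1_structure(C: np.ndarray, tip_h: np.ndarray, alpha: float) -> np.ndarray:
    """Fixed-root OU covariance with unit sigma2.

    V_ij = exp(-alpha d_ij) (1 - exp(-2 alpha s_ij)) / (2 alpha) with s the
    shared time and d the patristic separation; stable near alpha = 0 via
    expm1 (BM limit V = C).
    """
    if alpha <= 0:
        return C
    d = tip_h[:, None] + tip_h[None, :] - 2.0 * C
    return np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * C)) / (2.0 * alpha)


def fit_ou1(tree: Phylogeny, trait,
            alpha_bounds: tuple[float, float] | None = None) -> ModelFit:
    """Single-optimum OU fit: profile ML over alpha (theta, sigma2 analytic).

    The root state is fixed at the optimum, so on an ultrametric tree the
    mean vector is constant at theta.
    """
    x = trait_vector(tree, trait)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 species")
    C = phylo_covariance(tree).matrix
    tip_h = np.diag(C).copy()
    T = tree.height
    if alpha_bounds is None:
        alpha_bounds = (1e-8 / T, 100.0 / T)
    W = np.ones((n, 1))

    def negll(la: float) -> float:
        try:
            return -profiled_gaussian(_ou1_structure(C, tip_h, np.exp(la)), W, x)[0]
        except linalg.LinAlgError:
            return np.inf

    lo, hi = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])
    grid = np.linspace(lo, hi, 12)
    vals = np.array([negll(g) for g in grid])
    i = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        negll, bounds=(grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]),
        method="bounded", options={"xatol": 1e-9})
    cand = [(float(res.fun), float(res.x)), (float(vals[i]), float(grid[i]))]
    fbest, labest = min(cand)
    alpha_hat = float(np.exp(labest))
    logl, beta, s2, _ = profiled_gaussian(_ou1_structure(C, tip_h, alpha_hat), W, x)
    bound = alpha_hat >= alpha_bounds[1] * 0.999
    theta = float(beta[0])
    return ModelFit("OU1", {"": float(s2)}, {"": theta}, alpha_hat, None,
                    theta, float(logl), 4, _aicc_or_nan(logl, 4, n), n,
                    bound_hit=bound)


def ou1_loglik(tree: Phylogeny, trait, sigma2: float, alpha: float,
               theta: float) -> float:
    x = trait_vector(tree, trait)
    C = phylo_covariance(tree).matrix
    V = sigma2 * _ou1_structure(C, np.diag(C).copy(), alpha)
    return gaussian_loglik(V, np.full(len(x), theta), x)


# ---------------------------------------------------------------------- OUMV
class _OumvLik:
    """Precomputed regime-history structure for fast OUMV likelihoods.

    For a given alpha, builds per-regime covariance contributions
    A_s[i, j] = integral over the root->MRCA(i,j) path segments in regime s
    of exp(-2 alpha (T - u)) du, and the mean design W[i, s] = selection
    exposure of regime s along the root->tip path (rows sum to 1 including
    the root term), so that V = sum_s sigma2_s A_s and E[x] = W theta.
    """

    def __init__(self, tree: Phylogeny, regimes: RegimeHistory):
        if not tree.is_ultrametric(rtol=1e-6):
            raise ValueError("OUMV requires an ultrametric tree")
        self.tree = tree
        self.states = tuple(regimes.states)
        self.k = len(self.states)
        sidx = {s: i for i, s in enumerate(self.states)}
        seg_node, seg_state, seg_t0, seg_t1 = [], [], [], []
        present = set()
        for node in range(tree.n_nodes):
            for (t0, t1, st) in regimes.segments[node]:
                seg_node.append(node)
                seg_state.append(sidx[st])
                seg_t0.append(t0)
                seg_t1.append(t1)
                present.add(st)
        missing = [s for s in self.states if s not in present]
        if missing:
            raise ValueError(f"regimes absent from the history: {missing}")
        self.seg_node = np.asarray(seg_node, dtype=np.int64)
        self.seg_state = np.asarray(seg_state, dtype=np.int64)
        self.seg_t0 = np.asarray(seg_t0)
        self.seg_t1 = np.asarray(seg_t1)
        self.T = tree.height
        self.root_state = sidx[regimes.root_state]
        self.preorder = tree.preorder
        self.parent = tree.parent
        self.mrca = tree.mrca_matrix
        self.n = tree.n_tips

    def structure(self, alpha: float):
        """(A, W): per-regime covariance structure and mean design at alpha."""
        T, dt = self.T, self.seg_t1 - self.seg_t0
        if alpha <= 0:
            I = dt
            J = np.zeros_like(dt)
            root_w = 1.0
        else:
            e1 = np.exp(-2.0 * alpha * (T - self.seg_t1))
            I = e1 * (-np.expm1(-2.0 * alpha * dt)) / (2.0 * alpha)
            J = np.exp(-alpha * (T - self.seg_t1)) * (-np.expm1(-alpha * dt))
            root_w = np.exp(-alpha * T)
        nn = self.tree.n_nodes
        eIJ = np.zeros((nn, 2 * self.k))
        np.add.at(eIJ, (self.seg_node, self.seg_state), I)
        np.add.at(eIJ, (self.seg_node, self.k + self.seg_state), J)
        gb = self.tree.path_matrix @ eIJ  # accumulate along root->node paths
        g, b = gb[:, : self.k], gb[:, self.k:]
        A = np.empty((self.k, self.n, self.n))
        for s in range(self.k):
            A[s] = g[:, s][self.mrca]
        W = b[: self.n].copy()
        W[:, self.root_state] += root_w
        return A, W

    def profiled(self, alpha: float, ratios: np.ndarray):
        """Profiled logL with sigma2 of the first regime as the free scale.

        ``ratios`` are sigma2_s / sigma2_0 for regimes 1..k-1.
        """
        A, W = self.structure(alpha)
        V0 = A[0].copy()
        for s in range(1, self.k):
            V0 += ratios[s - 1] * A[s]
        return profiled_gaussian(V0, W, self.trait)


def fit_oumv(tree: Phylogeny, trait, regimes: RegimeHistory,
             alpha_bounds: tuple[float, float] | None = None,
             n_starts: int = 3, ou1_alpha: float | None = None,
             extra_starts: Sequence[np.ndarray] = ()) -> ModelFit:
    """Multi-regime OU fit: per-regime sigma2 and theta, one global alpha.

    Optimizes (log alpha, log sigma2-ratio) numerically with the optima and
    the base variance profiled analytically; multi-start, warm-started from
    the single-optimum OU fit so the likelihood nests OU1.
    """
    x = trait_vector(tree, trait)
    n = len(x)
    lik = _OumvLik(tree, regimes)
    if lik.k != 2:
        raise NotImplementedError("OUMV fitting supports exactly 2 regimes")
    lik.trait = x
    T = tree.height
    if alpha_bounds is None:
        alpha_bounds = (1e-8 / T, 100.0 / T)
    lo_a, hi_a = np.log(alpha_bounds[0]), np.log(alpha_bounds[1])
    lo_r, hi_r = np.log(1e-4), np.log(1e4)
    best = {"val": np.inf, "u": None}

    def negll(u: np.ndarray) -> float:
        la = np.clip(u[0], lo_a, hi_a)
        lr = np.clip(u[1], lo_r, hi_r)
        try:
            v = -lik.profiled(np.exp(la), np.array([np.exp(lr)]))[0]
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            return np.inf
        if v < best["val"]:
            best["val"], best["u"] = v, np.array([la, lr])
        return v

    if ou1_alpha is None:
        ou1_alpha = fit_ou1(tree, trait, alpha_bounds=alpha_bounds).alpha
    a0 = np.log(np.clip(ou1_alpha, alpha_bounds[0] * 1.01,
                        alpha_bounds[1] * 0.99))
    starts = [np.array([a0, 0.0]),
              np.array([np.log(5.0 / T), np.log(5.0)]),
              np.array([np.log(0.5 / T), np.log(0.2)])][:n_starts]
    starts.extend(np.asarray(u) for u in extra_starts)
    for u0 in starts:
        optimize.minimize(negll, u0, method="Nelder-Mead",
                          options={"xatol": 1e-4, "fatol": 1e-7,
                                   "maxiter": 150})
    if best["u"] is None:
        raise linalg.LinAlgError("OUMV likelihood surface is degenerate")
    la, lr = best["u"]
    alpha_hat, ratio = float(np.exp(la)), float(np.exp(lr))
    logl, beta, s2, _ = lik.profiled(alpha_hat, np.array([ratio]))
    s0, s1 = float(s2), float(s2 * ratio)
    states = lik.states
    sigma2 = {states[0]: s0, states[1]: s1}
    theta = {states[0]: float(beta[0]), states[1]: float(beta[1])}
    k = 6
    bound = not (lo_a + 1e-6 < la < hi_a - 1e-6)
    return ModelFit("OUMV", sigma2, theta, alpha_hat, None,
                    theta[regimes.root_state], float(logl), k,
                    _aicc_or_nan(logl, k, n), n, bound_hit=bound,
                    extras={"sigma2_ratio": ratio, "u": best["u"]})


def oumv_loglik(tree: Phylogeny, trait, regimes: RegimeHistory,
                alpha: float, sigma2: dict, theta: dict) -> float:
    """OUMV log-likelihood at fixed parameters (for oracle checks)."""
    x = trait_vector(tree, trait)
    lik = _OumvLik(tree, regimes)
    A, W = lik.structure(alpha)
    V = np.zeros_like(A[0])
    th = np.empty(lik.k)
    for s, name in enumerate(lik.states):
        V += sigma2[name] * A[s]
        th[s] = theta[name]
    return gaussian_loglik(V, W @ th, x)


# --------------------------------------------------------- stochastic mapping
def _mk_transition(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probabilities for a 2-state chain (closed form) or expm."""
    if Q.shape == (2, 2):
        s = Q[0, 1] + Q[1, 0]
        if s <= 0:
            return np.eye(2)
        pi = np.array([Q[1, 0], Q[0, 1]]) / s
        e = np.exp(-s * t)
        P = np.empty((2, 2))
        P[0] = pi + e * (np.array([1.0, 0.0]) - pi)
        P[1] = pi + e * (np.array([0.0, 1.0]) - pi)
        return P
    return linalg.expm(Q * t)


def _mk_partials(tree: Phylogeny, tip_idx: np.ndarray, Q: np.ndarray):
    k = Q.shape[0]
    L = np.zeros((tree.n_nodes, k))
    L[np.arange(tree.n_tips), tip_idx] = 1.0
    for node in tree.postorder:
        if tree.is_tip(node):
            continue
        prod = np.ones(k)
        for c in tree.children[node]:
            P = _mk_transition(Q, tree.edge_length[c])
            prod = prod * (P @ L[c])
        L[node] = prod
    return L


def _mk_loglik(tree: Phylogeny, tip_idx: np.ndarray, Q: np.ndarray) -> float:
    L = _mk_partials(tree, tip_idx, Q)
    k = Q.shape[0]
    root = float((L[tree.root] / k).sum())
    if root <= 0:
        return -np.inf
    return np.log(root)


def fit_mk(tree: Phylogeny, tip_states: pd.Series,
           states: Sequence[str] = ("plant", "ground"),
           model: str = "ER") -> np.ndarray:
    """ML rate matrix of the Mk model (ER: one rate; ARD: one per direction)."""
    states = tuple(states)
    sidx = {s: i for i, s in enumerate(states)}
    tip_idx = np.asarray([sidx[tip_states[lab]] for lab in tree.tip_labels])
    if len(np.unique(tip_idx)) < 2:
        raise ValueError("need at least 2 observed states to fit a rate matrix")
    k = len(states)
    T = tree.height

    def build(rates: np.ndarray) -> np.ndarray:
        Q = np.zeros((k, k))
        if model == "ER":
            Q[:] = rates[0]
        else:  # ARD, 2 states
            Q[0, 1], Q[1, 0] = rates
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    if model == "ER":
        res = optimize.minimize_scalar(
            lambda lq: -_mk_loglik(tree, tip_idx, build(np.array([np.exp(lq)]))),
            bounds=(np.log(1e-6 / T), np.log(100.0 / T)), method="bounded")
        return build(np.array([np.exp(res.x)]))
    if model != "ARD" or k != 2:
        raise NotImplementedError("models supported: ER (any k=2), ARD (2 states)")
    res = optimize.minimize(
        lambda lq: -_mk_loglik(tree, tip_idx, build(np.exp(lq))),
        np.log([1.0 / T, 1.0 / T]), method="Nelder-Mead")
    return build(np.exp(res.x))


def _sample_path(Q: np.ndarray, a: int, b: int, t: float,
                 rng: np.random.Generator, max_tries: int = 100):
    """Endpoint-conditioned CTMC path as a list of (dt, state) segments.

    Rejection sampling (with first-jump conditioning when a != b) and a
    uniformization fallback.
    """
    k = Q.shape[0]
    exit_rate = -np.diag(Q)
    jump_p = Q.copy()
    np.fill_diagonal(jump_p, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_p = np.where(exit_rate[:, None] > 0, jump_p / exit_rate[:, None], 0.0)

    for _ in range(max_tries):
        path = []
        s, tau = a, 0.0
        if a != b:
            rate = exit_rate[a]
            if rate <= 0:
                break
            u = rng.uniform()
            tau = -np.log1p(u * np.expm1(-rate * t)) / rate  # truncated exp
            path.append((tau, a))
            s = int(rng.choice(k, p=jump_p[a]))
        while True:
            rate = exit_rate[s]
            dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if tau + dt >= t:
                path.append((t - tau, s))
                break
            path.append((dt, s))
            tau += dt
            s = int(rng.choice(k, p=jump_p[s]))
        if s == b:
            return path

    # uniformization fallback
    om = float(exit_rate.max())
    if om <= 0:
        return [(t, a)]
    R = np.eye(k) + Q / om
    Pt = _mk_transition(Q, t)
    target = Pt[a, b]
    # sample the number of uniformized jumps N | endpoints
    u = rng.uniform()
    cum = 0.0
    pois = np.exp(-om * t)
    Rn = np.eye(k)
    N = 0
    for n_jump in range(0, 500):
        cum += pois * Rn[a, b] / target
        if u <= cum:
            N = n_jump
            break
        pois *= om * t / (n_jump + 1)
        Rn = Rn @ R
    else:
        N = 500
    if N == 0:
        return [(t, a)]
    # powers of R for the state bridge
    powers = [np.eye(k)]
    for _ in range(N):
        powers.append(powers[-1] @ R)
    states_seq = [a]
    for j in range(1, N):
        prev = states_seq[-1]
        w = R[prev] * powers[N - j][:, b]
        states_seq.append(int(rng.choice(k, p=w / w.sum())))
    states_seq.append(b)
    jump_times = np.sort(rng.uniform(0.0, t, size=N))
    bounds = np.concatenate([[0.0], jump_times, [t]])
    path = []
    for j, s in enumerate(states_seq):
        dt = bounds[j + 1] - bounds[j]
        if path and path[-1][1] == s:
            path[-1] = (path[-1][0] + dt, s)
        else:
            path.append((dt, s))
    return path


def stochastic_maps(tree: Phylogeny, tip_states: pd.Series, n_maps: int = 500,
                    model: str = "ER", seed: int | None = 0,
                    states: Sequence[str] = ("plant", "ground"),
                    rng: np.random.Generator | None = None,
                    q_matrix: np.ndarray | None = None) -> list[RegimeHistory]:
    """Sample full regime histories consistent with the observed tip states.

    The Mk rate matrix is fitted by ML (unless supplied), node states are
    drawn from their conditional distributions, and endpoint-conditioned
    paths are sampled along each branch. Every history reproduces the tip
    states exactly and tiles every edge.
    """
    states = tuple(states)
    sidx = {s: i for i, s in enumerate(states)}
    tip_idx = np.asarray([sidx[tip_states[lab]] for lab in tree.tip_labels])
    if len(np.unique(tip_idx)) < 2:
        raise ValueError("invariant tip states: no mapping possible")
    Q = fit_mk(tree, tip_states, states, model) if q_matrix is None else np.asarray(q_matrix, float)
    if rng is None:
        rng = np.random.default_rng(seed)
    k = len(states)
    partials = _mk_partials(tree, tip_idx, Q)
    h = tree.node_heights
    prior = np.full(k, 1.0 / k)
    # cache transition matrices per edge
    P_edge = {int(node): _mk_transition(Q, tree.edge_length[node])
              for node in range(tree.n_nodes) if node != tree.root}
    maps = []
    for _ in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=np.int64)
        w = prior * partials[tree.root]
        node_state[tree.root] = rng.choice(k, p=w / w.sum())
        for node in tree.preorder:
            for c in tree.children[node]:
                if tree.is_tip(c):
                    node_state[c] = tip_idx[c]
                    continue
                w = P_edge[c][node_state[node]] * partials[c]
                node_state[c] = rng.choice(k, p=w / w.sum())
        segments: list[list] = [[] for _ in range(tree.n_nodes)]
        for node in tree.preorder:
            p = tree.parent[node]
            if p < 0:
                continue
            t = float(tree.edge_length[node])
            if t <= 0:
                segments[node] = [(float(h[p]), float(h[node]),
                                   states[node_state[node]])]
                continue
            path = _sample_path(Q, int(node_state[p]), int(node_state[node]),
                                t, rng)
            t0 = float(h[p])
            segs = []
            for dt, s in path:
                segs.append((t0, t0 + dt, states[s]))
                t0 += dt
            # snap the endpoint to the node height exactly
            last = segs[-1]
            segs[-1] = (last[0], float(h[node]), last[2])
            segments[node] = segs
        tips = pd.Series([states[i] for i in tip_idx], index=tree.tip_labels)
        maps.append(RegimeHistory(states, segments, tips,
                                  states[node_state[tree.root]]))
    return maps


# ------------------------------------------------------------ model comparison
@dataclass
class ModelComparison:
    table: pd.DataFrame
    fits: dict
    best_model: str
    n_maps: int
    oumv_aiccs: np.ndarray
    n_failed_maps: int = 0

    def __str__(self) -> str:  # pragma: no cover
        return self.table.to_string()


def compare_models(tree: Phylogeny, trait, tip_states: pd.Series,
                   n_maps: int = 500, seed: int | None = 0,
                   rng: np.random.Generator | None = None,
                   maps: list[RegimeHistory] | None = None) -> ModelComparison:
    """Fit BM, EB, OU1 once and OUMV across sampled regime histories.

    The OUMV AICc is the arithmetic mean over the per-map fits; delta-AICc is
    each model's (mean) AICc minus the minimum across models. Maps whose fit
    fails are dropped; more than 10% failures is an error.
    """
    fits = {
        "BM": fit_bm(tree, trait),
        "EB": fit_eb(tree, trait),
        "OU1": fit_ou1(tree, trait),
    }
    if maps is None:
        maps = stochastic_maps(tree, tip_states, n_maps=n_maps, seed=seed,
                               rng=rng)
    per_map = []
    oumv_fits = []
    failed = 0
    prev_u = None
    for hist in maps:
        try:
            f = fit_oumv(tree, trait, hist, ou1_alpha=fits["OU1"].alpha,
                         n_starts=3 if prev_u is None else 1,
                         extra_starts=() if prev_u is None else (prev_u,))
            prev_u = f.extras["u"]
            per_map.append(f.aicc)
            oumv_fits.append(f)
        except (ValueError, linalg.LinAlgError, np.linalg.LinAlgError):
            failed += 1
    if failed > 0.1 * len(maps):
        raise RuntimeError(f"{failed}/{len(maps)} OUMV map fits failed")
    oumv_aiccs = np.asarray(per_map)
    states = maps[0].states
    rep = oumv_fits[int(np.argmin(np.abs(oumv_aiccs - oumv_aiccs.mean())))]
    fits["OUMV"] = rep
    mean_aicc = {m: fits[m].aicc for m in ("BM", "EB", "OU1")}
    mean_aicc["OUMV"] = float(oumv_aiccs.mean())
    amin = min(mean_aicc.values())
    rows = []
    for m in ("BM", "EB", "OU1", "OUMV"):
        f = fits[m]
        if m == "OUMV":
            s_p, s_g = f.sigma2[states[0]], f.sigma2[states[1]]
            t_p, t_g = f.theta[states[0]], f.theta[states[1]]
        else:
            s_p = s_g = f.sigma2_scalar
            t_p = t_g = f.theta[""] if f.theta else np.nan
        rows.append({
            "model": m, "AICc": mean_aicc[m],
            "dAICc": mean_aicc[m] - amin,
            f"sigma2_{states[0]}": s_p, f"theta_{states[0]}": t_p,
            f"sigma2_{states[1]}": s_g, f"theta_{states[1]}": t_g,
        })
    table = pd.DataFrame(rows).set_index("model")
    best = table["AICc"].idxmin()
    return ModelComparison(table, fits, str(best), len(maps), oumv_aiccs,
                           failed)
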