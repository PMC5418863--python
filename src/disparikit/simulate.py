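"""Synthetic study generators with known ground truth.

Emulates the data shapes of a continental grasshopper radiation study: a
~70-tip time-calibrated Yule tree, continuous traits evolved under BM / EB /
OU (optionally with substrate-regime-dependent optima and rates), a discrete
substrate-guild history, 14-landmark 2D head configurations with digitization
noise, and a species x 9-habitat association matrix with integer scores 0-3.

All generators are reproducible: equal seeds give bitwise-equal outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .tree import Phylogeny, phylo_covariance
from .morpho import LandmarkSet

__all__ = [
    "SimulationConfig",
    "RegimeHistory",
    "stream",
    "simulate_yule",
    "simulate_trait",
    "simulate_mk",
    "simulate_landmarks",
    "simulate_habitat_matrix",
    "default_head_shape",
    "SyntheticStudy",
    "make_study",
]


def stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream derived from a root seed.

    Stage streams are independent, so changing the number of draws in one
    stage never perturbs another.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# --------------------------------------------------------------------- config
@dataclass
class SimulationConfig:
    """Parameters of a synthetic trait/tree study.

    Regime-keyed parameters (``sigma2``, ``theta``) may be scalars (shared) or
    ``{regime: value}`` mappings for the multi-regime OU models.
    """

    n_tips: int = 70
    birth_rate: float = 1.0
    seed: int = 0
    model: str = "BM"  # BM | EB | OU1 | OUM | OUMV
    sigma2: float | Mapping[str, float] = 1.0
    theta: float | Mapping[str, float] = 0.0
    alpha: float = 0.0
    eb_rate: float = 0.0  # a <= 0
    z0: float = 0.0
    q_matrix: Optional[np.ndarray] = None
    regime_states: tuple[str, ...] = ("plant", "ground")
    landmark_noise: float = 0.01
    shape_sigma2: float = 1e-4
    n_specimens: tuple[int, int] = (3, 5)
    n_habitats: int = 9

    def sigma2_for(self, regime: str) -> float:
        if isinstance(self.sigma2, Mapping):
            return float(self.sigma2[regime])
        return float(self.sigma2)

    def theta_for(self, regime: str) -> float:
        if isinstance(self.theta, Mapping):
            return float(self.theta[regime])
        return float(self.theta)


# ------------------------------------------------------------- regime history
@dataclass
class RegimeHistory:
    """A painting of discrete states onto every point of every branch.

    ``segments[node]`` lists ``(t_start, t_end, state)`` tuples (absolute time
    from the root) tiling the edge above ``node``; the root has no edge and an
    empty list. ``tip_states`` gives the state at each tip.
    """

    states: tuple[str, ...]
    segments: list[list[tuple[float, float, str]]]
    tip_states: pd.Series
    root_state: str

    def n_changes(self) -> int:
        total = 0
        prev_state_of = {}
        for node, segs in enumerate(self.segments):
            for i in range(1, len(segs)):
                if segs[i][2] != segs[i - 1][2]:
                    total += 1
            prev_state_of[node] = segs
        return total

    def validate(self, tree: Phylogeny, tol: float = 1e-12) -> None:
        h = tree.node_heights
        scale = max(tree.height, 1.0)
        for node in range(tree.n_nodes):
            p = tree.parent[node]
            segs = self.segments[node]
            if p < 0:
                if segs:
                    raise ValueError("root must have no edge segments")
                continue
            if not segs:
                raise ValueError(f"edge above node {node} has no segments")
            if abs(segs[0][0] - h[p]) > tol * scale or abs(segs[-1][1] - h[node]) > tol * scale:
                raise ValueError(f"segments do not span edge above node {node}")
            for (a0, a1, _), (b0, _, _) in zip(segs, segs[1:]):
                if abs(a1 - b0) > tol * scale:
                    raise ValueError(f"gap/overlap in segments above node {node}")
        for lab, st in self.tip_states.items():
            node = tree.tip_index[lab]
            if self.segments[node][-1][2] != st:
                raise ValueError(f"tip state inconsistent with last segment at {lab}")


def uniform_history(tree: Phylogeny, state: str, states=("plant", "ground")) -> RegimeHistory:
    """Single-state history covering the whole tree (useful for testing)."""
    h = tree.node_heights
    segments: list[list] = [[] for _ in range(tree.n_nodes)]
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0:
            segments[node] = [(float(h[p]), float(h[node]), state)]
    tips = pd.Series(state, index=tree.tip_labels)
    return RegimeHistory(tuple(states), segments, tips, state)


# ----------------------------------------------------------------------- tree
def simulate_yule(n_tips: int, birth_rate: float = 1.0, seed: int | None = 0,
                  rng: np.random.Generator | None = None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with exactly ``n_tips`` tips.

    Waiting times between successive splits are Exp(k * birth_rate) with k the
    current lineage count; after the last split the present is set a further
    Exp(n * birth_rate) later so terminal branches are positive.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    width = len(str(n_tips))
    t = 0.0
    root = {"birth": 0.0, "split": None, "kids": None}
    active = [root]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = active.pop(int(rng.integers(k)))
        node["split"] = t
        node["kids"] = [{"birth": t, "split": None, "kids": None},
                        {"birth": t, "split": None, "kids": None}]
        active.extend(node["kids"])
    present = t + rng.exponential(1.0 / (n_tips * birth_rate))
    labels = [f"s{str(i + 1).zfill(width)}" for i in range(n_tips)]
    rng.shuffle(labels)
    label_iter = iter(labels)

    def to_nested(node):
        if node["kids"] is None:
            return (next(label_iter), present - node["birth"], None)
        return (None, node["split"] - node["birth"],
                [to_nested(c) for c in node["kids"]])

    return Phylogeny.from_nested(to_nested(root))


# ------------------------------------------------------------------- Mk model
def simulate_mk(tree: Phylogeny, q_matrix, root_state: str,
                seed: int | None = 0, states: Sequence[str] = ("plant", "ground"),
                rng: np.random.Generator | None = None) -> RegimeHistory:
    """Exact Gillespie simulation of a continuous-time Markov chain on the tree."""
    if rng is None:
        rng = np.random.default_rng(seed)
    states = tuple(states)
    Q = np.asarray(q_matrix, dtype=float)
    k = len(states)
    if Q.shape != (k, k):
        raise ValueError("q_matrix shape does not match state alphabet")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal rates must be nonnegative")
    exit_rate = off.sum(axis=1)
    h = tree.node_heights
    state_idx = {s: i for i, s in enumerate(states)}
    node_state = np.empty(tree.n_nodes, dtype=np.int64)
    node_state[tree.root] = state_idx[root_state]
    segments: list[list] = [[] for _ in range(tree.n_nodes)]
    for node in tree.preorder:
        p = tree.parent[node]
        if p < 0:
            continue
        s = node_state[p]
        t0, t1 = float(h[p]), float(h[node])
        segs = []
        t = t0
        while True:
            rate = exit_rate[s]
            if rate <= 0:
                segs.append((t, t1, states[s]))
                break
            dt = rng.exponential(1.0 / rate)
            if t + dt >= t1:
                segs.append((t, t1, states[s]))
                break
            segs.append((t, t + dt, states[s]))
            t += dt
            s = rng.choice(k, p=off[s] / rate)
        node_state[node] = s
        segments[node] = segs
    tip_states = pd.Series(
        [states[node_state[i]] for i in range(tree.n_tips)], index=tree.tip_labels
    )
    return RegimeHistory(states, segments, tip_states, root_state)


# ------------------------------------------------------------------ trait sim
def _ou_step(x, theta, alpha, sigma2, dt, rng):
    if alpha <= 0:
        return x + rng.normal(0.0, np.sqrt(sigma2 * dt)) if dt > 0 else x
    mean = theta + (x - theta) * np.exp(-alpha * dt)
    var = sigma2 * -np.expm1(-2 * alpha * dt) / (2 * alpha)
    return rng.normal(mean, np.sqrt(var))


def simulate_trait(tree: Phylogeny, config: SimulationConfig,
                   regimes: RegimeHistory | None = None,
                   rng: np.random.Generator | None = None) -> pd.Series:
    """Simulate a continuous trait along the tree under the configured model.

    BM increments are Normal(0, sigma2*dt); OU uses the exact Gaussian
    transition; EB uses the time-inhomogeneous rate sigma2 * exp(a*t).
    Regime switches within a branch split the OU transition at the switch
    point, using the regime in force over each sub-interval.
    """
    model = config.model.upper()
    if model in ("OUM", "OUMV") and regimes is None:
        raise ValueError(f"model {model} requires a RegimeHistory")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h = tree.node_heights
    x = np.empty(tree.n_nodes)
    x[tree.root] = config.z0
    for node in tree.preorder:
        p = tree.parent[node]
        if p < 0:
            continue
        t0, t1 = float(h[p]), float(h[node])
        val = x[p]
        if model == "BM":
            dt = t1 - t0
            val = val + rng.normal(0.0, np.sqrt(config.sigma2_for("") * dt)) if dt > 0 else val
        elif model == "EB":
            a = config.eb_rate
            if a > 0:
                raise ValueError("EB rate must be <= 0")
            s2 = config.sigma2_for("")
            var = s2 * ((np.exp(a * t1) - np.exp(a * t0)) / a if a != 0 else (t1 - t0))
            val = rng.normal(val, np.sqrt(var)) if var > 0 else val
        elif model == "OU1":
            val = _ou_step(val, config.theta_for(""), config.alpha,
                           config.sigma2_for(""), t1 - t0, rng)
        else:  # OUM / OUMV: piecewise by regime segment
            for (s0, s1, state) in regimes.segments[node]:
                s2 = config.sigma2_for(state) if model == "OUMV" else config.sigma2_for("")
                val = _ou_step(val, config.theta_for(state), config.alpha,
                               s2, s1 - s0, rng)
        x[node] = val
    return pd.Series(x[: tree.n_tips], index=tree.tip_labels)


# ------------------------------------------------------------------ landmarks
def default_head_shape() -> np.ndarray:
    """A stylized, centered 14-landmark 2D head outline (side view).

    Twelve landmarks on an elongated outline plus two marking the eye.
    """
    ang = np.linspace(0.0, 2 * np.pi, 12, endpoint=False)
    outline = np.column_stack([1.4 * np.cos(ang), 0.9 * np.sin(ang)])
    eye = np.array([[0.45, 0.35], [0.75, 0.25]])
    pts = np.vstack([outline, eye])
    return pts - pts.mean(axis=0)


def simulate_landmarks(tree: Phylogeny, mean_shape: np.ndarray | None = None,
                       shape_sigma2: float = 1e-4, noise: float = 0.01,
                       n_specimens: int | tuple[int, int] = (3, 5),
                       seed: int | None = 0,
                       rng: np.random.Generator | None = None) -> LandmarkSet:
    """Landmark configurations: BM shape deviations + digitization noise.

    Species-level deviations of each coordinate evolve by Brownian motion on
    the tree (rate ``shape_sigma2`` per unit time); each specimen adds
    isotropic Gaussian noise, then a random similarity transform (rotation
    Uniform(0, 2pi), log-scale Normal(0, 0.1), translation) is applied so the
    Procrustes superimposition downstream has real work to do.
    """
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    if mean_shape is None:
        mean_shape = default_head_shape()
    mean_shape = np.asarray(mean_shape, dtype=float)
    k = mean_shape.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    n = tree.n_tips
    C = phylo_covariance(tree).matrix
    if shape_sigma2 > 0:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(n) * max(tree.height, 1.0))
        dev = np.sqrt(shape_sigma2) * (L @ rng.standard_normal((n, 2 * k)))
    else:
        dev = np.zeros((n, 2 * k))
    if isinstance(n_specimens, int):
        lo = hi = n_specimens
    else:
        lo, hi = n_specimens
    ids, species, coords, scales = [], [], [], []
    for i, lab in enumerate(tree.tip_labels):
        spp_shape = mean_shape + dev[i].reshape(k, 2)
        m = int(rng.integers(lo, hi + 1))
        for j in range(m):
            cfg = spp_shape + rng.normal(0.0, noise, size=(k, 2)) if noise > 0 else spp_shape.copy()
            ang = rng.uniform(0.0, 2 * np.pi)
            scale = float(np.exp(rng.normal(0.0, 0.1)))
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            shift = rng.normal(0.0, 1.0, size=2)
            cfg = scale * cfg @ R.T + shift
            ids.append(f"{lab}_{j + 1:02d}")
            species.append(lab)
            coords.append(cfg)
            scales.append(scale)
    return LandmarkSet(ids, species, np.asarray(coords), np.asarray(scales))


# --------------------------------------------------------------- habitat data
def simulate_habitat_matrix(specialization, seed: int | None = 0,
                            n_habitats: int = 9,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Species x habitat association scores (integers 0-3).

    ``specialization`` in [0, 1] per species: 1 gives one habitat scored 3 and
    the rest 0 (complete specialist); 0 gives a uniform row (complete
    generalist); intermediate values interpolate the secondary-habitat score
    3*(1-s) deterministically before rounding. Which habitat is primary is
    randomized per species.
    """
    if isinstance(specialization, Mapping):
        specialization = pd.Series(specialization)
    if not isinstance(specialization, pd.Series):
        specialization = pd.Series(np.asarray(specialization, dtype=float),
                                   index=[f"s{i+1}" for i in range(len(specialization))])
    s = specialization.to_numpy(dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("specialization values must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(s)
    M = np.rint(3.0 * (1.0 - s))[:, None] * np.ones((1, n_habitats))
    primary = rng.integers(n_habitats, size=n)
    M[np.arange(n), primary] = 3
    cols = [f"habitat_{i + 1}" for i in range(n_habitats)]
    return pd.DataFrame(M.astype(int), index=specialization.index, columns=cols)


# ------------------------------------------------------------------ the study
@dataclass
class SyntheticStudy:
    """A full synthetic dataset mirroring the study's five inputs, plus truth."""

    tree: Phylogeny
    traits: pd.DataFrame  # body/tibia/femur/tegmina/antenna lengths (raw, mm-like)
    landmarks: LandmarkSet
    guilds: pd.Series  # species -> plant|ground
    habitats: pd.DataFrame  # species x 9 integer scores
    regime_history: RegimeHistory
    truth: dict = field(default_factory=dict)


def make_study(seed: int = 0, n_tips: int = 70, tree_height: float = 100.0,
               pgls_effect: float = 0.3) -> SyntheticStudy:
    """Generate the default synthetic study.

    Conditions emulate the study system: 70 species on a height-100 (Mya-like)
    Yule tree; two substrate guilds evolving under a symmetric Markov chain
    (expected ~2 transitions root-to-tip); log linear traits with isometric
    allometry on structural body length plus Brownian deviations; a
    guild-dependent OU deviation on the femur width/length ratio and tegmina;
    relative antenna length tied to ecological specialization with slope
    ``pgls_effect``; 14-landmark heads with BM shape deviations and
    digitization noise; and a 9-habitat association matrix.
    """
    tree = simulate_yule(n_tips, 1.0, rng=stream(seed, "tree")).rescale(tree_height)
    T = tree.height

    # substrate guild history: symmetric rates, both states guaranteed present
    q = 2.0 / T
    Q = np.array([[-q, q], [q, -q]])
    rng_mk = stream(seed, "guild")
    for _ in range(100):
        hist = simulate_mk(tree, Q, "ground", rng=rng_mk)
        counts = hist.tip_states.value_counts()
        if len(counts) == 2 and counts.min() >= 5:
            break
    guilds = hist.tip_states

    def bm(name, sigma2_total, z0=0.0):
        cfg = SimulationConfig(model="BM", sigma2=sigma2_total / T, z0=z0)
        return simulate_trait(tree, cfg, rng=stream(seed, name))

    # log-scale traits (mm); structural body length ~ 20 mm
    log_body = bm("body", 0.05, np.log(20.0))
    log_tibia = log_body + bm("tibia", 0.02, np.log(0.45))
    log_femur_len = log_body + bm("femur_len", 0.02, np.log(0.55))
    # femur width/length ratio: OU toward guild-dependent optima (stouter on ground)
    ratio_cfg = SimulationConfig(
        model="OUMV", alpha=3.0 / T,
        sigma2={"plant": 0.02 / T, "ground": 0.04 / T},
        theta={"plant": np.log(0.18), "ground": np.log(0.25)},
        z0=np.log(0.25),
    )
    log_ratio = simulate_trait(tree, ratio_cfg, regimes=hist, rng=stream(seed, "ratio"))
    log_femur_wid = log_femur_len + log_ratio
    # tegmina: longer-winged on plants
    teg_cfg = SimulationConfig(
        model="OUMV", alpha=3.0 / T,
        sigma2={"plant": 0.03 / T, "ground": 0.05 / T},
        theta={"plant": np.log(0.9), "ground": np.log(0.6)},
        z0=np.log(0.6),
    )
    log_teg = log_body + simulate_trait(tree, teg_cfg, regimes=hist, rng=stream(seed, "tegmina"))

    # specialization with phylogenetic structure -> habitat matrix & PDI truth
    spec_raw = bm("specialization", 1.0)
    s = (spec_raw - spec_raw.min()) / (spec_raw.max() - spec_raw.min())
    habitats = simulate_habitat_matrix(s, rng=stream(seed, "habitats"))
    # relative antenna length responds to specialization (slope = pgls_effect)
    log_ant = (log_body + np.log(0.4) + pgls_effect * s
               + bm("antenna", 0.02))

    traits = pd.DataFrame({
        "body_length": np.exp(log_body),
        "tibia_length": np.exp(log_tibia),
        "femur_width": np.exp(log_femur_wid),
        "femur_length": np.exp(log_femur_len),
        "tegmina_length": np.exp(log_teg),
        "antenna_length": np.exp(log_ant),
    })
    traits.index.name = "species"

    landmarks = simulate_landmarks(
        tree, shape_sigma2=2e-4 / T, noise=0.01, n_specimens=(3, 5),
        rng=stream(seed, "landmarks"),
    )
    truth = {"specialization": s, "pgls_effect": pgls_effect,
             "ratio_theta": ratio_cfg.theta, "tegmina_theta": teg_cfg.theta,
             "guild_rate": q}
    return SyntheticStudy(tree, traits, landmarks, guilds, habitats, hist, truth)
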