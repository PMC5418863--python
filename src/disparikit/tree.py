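"""Phylogeny container, Newick I/O, and the Brownian-motion linear algebra kernel.

The :class:`Phylogeny` is an immutable array-backed rooted bifurcating tree with
branch lengths in time units (Mya by convention; no unit conversion is done).
Every comparative method in the package reduces to Gaussian linear algebra on
the phylogenetic covariance matrix built here, or to Felsenstein pruning passes
over the same arrays.

Polytomies in input trees are resolved deterministically (children ordered by
their smallest descendant label, then laddered) into zero-length internal
branches, which leaves the induced covariance unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "Phylogeny",
    "PhyloCovariance",
    "ContrastSet",
    "read_newick",
    "load_newick",
    "write_newick",
    "phylo_covariance",
    "lambda_transform",
    "eb_transform",
    "independent_contrasts",
    "ancestral_states_ml",
    "edge_interpolation",
    "prune_to_subset",
]


class NewickError(ValueError):
    """Malformed Newick input (parse failure or missing branch length)."""


# A nested node is (label, edge_length, children); children is None for leaves.
_Nested = tuple


def _min_label(node: _Nested) -> str:
    label, _, kids = node
    if kids is None:
        return label
    return min(_min_label(k) for k in kids)


def _resolve_polytomies(node: _Nested) -> _Nested:
    label, length, kids = node
    if kids is None:
        return node
    kids = sorted((_resolve_polytomies(k) for k in kids), key=_min_label)
    while len(kids) > 2:
        merged = (None, 0.0, [kids[0], kids[1]])
        kids = [merged] + kids[2:]
    if len(kids) == 1:
        # degree-1 internal node: splice it out, summing lengths
        clabel, clen, ckids = kids[0]
        return (clabel, length + clen, ckids)
    return (label, length, kids)


class Phylogeny:
    """Rooted bifurcating tree with branch lengths.

    Node indexing: tips occupy ``0 .. n_tips-1`` ordered alphabetically by
    label; internal nodes follow. ``parent[root] == -1`` and
    ``edge_length[root] == 0``.
    """

    def __init__(
        self,
        tip_labels: Sequence[str],
        parent: np.ndarray,
        edge_length: np.ndarray,
        children: Sequence[Sequence[int]],
        root: int,
    ):
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.children = [list(c) for c in children]
        self.root = int(root)
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels must be unique")
        if np.any(self.edge_length < 0):
            raise ValueError("branch lengths must be nonnegative")
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    @cached_property
    def preorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return np.asarray(order, dtype=np.int64)

    @cached_property
    def postorder(self) -> np.ndarray:
        # reversed preorder visits all children before their parent
        return self.preorder[::-1].copy()

    @cached_property
    def node_heights(self) -> np.ndarray:
        """Time elapsed from the root (root = 0, tips = tree height)."""
        h = np.zeros(self.n_nodes)
        for node in self.preorder:
            p = self.parent[node]
            if p >= 0:
                h[node] = h[p] + self.edge_length[node]
        return h

    @property
    def tip_heights(self) -> np.ndarray:
        return self.node_heights[: self.n_tips]

    @property
    def height(self) -> float:
        return float(self.tip_heights.max())

    def is_ultrametric(self, rtol: float = 1e-8) -> bool:
        h = self.tip_heights
        return bool(np.ptp(h) <= rtol * max(h.max(), np.finfo(float).tiny))

    @cached_property
    def clade_tips(self) -> list[np.ndarray]:
        """Tip indices descending from each node (tips include themselves)."""
        clades: list = [None] * self.n_nodes
        for node in self.postorder:
            if self.is_tip(node):
                clades[node] = np.array([node], dtype=np.int64)
            else:
                clades[node] = np.concatenate([clades[c] for c in self.children[node]])
        return clades

    @cached_property
    def path_matrix(self) -> np.ndarray:
        """P[node, anc] = 1 if the edge above ``anc`` lies on the root->node path."""
        P = np.zeros((self.n_nodes, self.n_nodes))
        for node in self.preorder:
            p = self.parent[node]
            if p >= 0:
                P[node] = P[p]
                P[node, node] = 1.0
        return P

    @cached_property
    def mrca_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of MRCA node indices (diagonal = tip itself)."""
        n = self.n_tips
        M = np.empty((n, n), dtype=np.int64)
        M[np.diag_indices(n)] = np.arange(n)
        clades = self.clade_tips
        for node in self.postorder:
            if self.is_tip(node):
                continue
            kids = self.children[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ta, tb = clades[kids[a]], clades[kids[b]]
                    M[np.ix_(ta, tb)] = node
                    M[np.ix_(tb, ta)] = node
        return M

    # --------------------------------------------------------------- builders
    @classmethod
    def from_nested(cls, nested: _Nested) -> "Phylogeny":
        nested = _resolve_polytomies(nested)
        labels: list[str] = []

        def collect(node):
            label, _, kids = node
            if kids is None:
                labels.append(label)
            else:
                for k in kids:
                    collect(k)

        collect(nested)
        tip_labels = sorted(labels)
        tip_index = {lab: i for i, lab in enumerate(tip_labels)}
        n_tips = len(tip_labels)
        n_nodes = 2 * n_tips - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        edge_length = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        counter = [n_tips]

        def build(node) -> int:
            label, length, kids = node
            if kids is None:
                idx = tip_index[label]
            else:
                kid_idx = [build(k) for k in kids]
                idx = counter[0]
                counter[0] += 1
                children[idx] = kid_idx
                for c in kid_idx:
                    parent[c] = idx
            edge_length[idx] = length
            return idx

        root = build(nested)
        edge_length[root] = 0.0
        return cls(tip_labels, parent, edge_length, children, root)

    def to_nested(self) -> _Nested:
        def rec(node: int) -> _Nested:
            if self.is_tip(node):
                return (self.tip_labels[node], float(self.edge_length[node]), None)
            return (None, float(self.edge_length[node]), [rec(c) for c in self.children[node]])

        return rec(self.root)

    def rescale(self, new_height: float) -> "Phylogeny":
        """Return a copy with all branch lengths multiplied so height == new_height."""
        f = new_height / self.height
        return Phylogeny(
            self.tip_labels, self.parent.copy(), self.edge_length * f,
            self.children, self.root,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, height {self.height:.4g}>"


# ---------------------------------------------------------------------- I/O
def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are mandatory on every edge except the root edge; a missing
    one is an error rather than a silent zero. Polytomies are resolved
    deterministically into zero-length branches.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy errors carry line/column context
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(node) -> _Nested:
        kids = node.child_nodes()
        length = node.edge.length
        if not kids:
            if node.taxon is None or node.taxon.label is None:
                raise NewickError("unlabeled tip in Newick input")
            if length is None:
                raise NewickError(
                    f"missing branch length on tip '{node.taxon.label}'"
                )
            return (node.taxon.label, float(length), None)
        if length is None:
            if node.parent_node is not None:
                raise NewickError("missing branch length on an internal edge")
            length = 0.0
        return (None, float(length), [convert(k) for k in kids])

    tree = Phylogeny.from_nested(convert(dtree.seed_node))
    if not tree.is_ultrametric():
        warnings.warn("input tree is not ultrametric within tolerance", stacklevel=2)
    return tree


def load_newick(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: Phylogeny, digits: int = 17) -> str:
    def fmt(x: float) -> str:
        return format(x, f".{digits}g")

    def rec(node: int) -> str:
        if tree.is_tip(node):
            lab = tree.tip_labels[node]
            if any(ch in lab for ch in " \t(),:;'"):
                lab = "'" + lab.replace("'", "''") + "'"
            return f"{lab}:{fmt(tree.edge_length[node])}"
        inner = ",".join(rec(c) for c in tree.children[node])
        if node == tree.root:
            return f"({inner})"
        return f"({inner}):{fmt(tree.edge_length[node])}"

    return rec(tree.root) + ";"


# ----------------------------------------------------------------- covariance
@dataclass
class PhyloCovariance:
    """Expected BM covariance among tips: shared root-to-MRCA path lengths."""

    matrix: np.ndarray
    species_order: list[str]

    def copy(self) -> "PhyloCovariance":
        return PhyloCovariance(self.matrix.copy(), list(self.species_order))


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """C[i,j] = shared path length of tips i and j; C[i,i] = depth of tip i."""
    h = tree.node_heights
    C = h[tree.mrca_matrix]
    return PhyloCovariance(C, list(tree.tip_labels))


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: multiply off-diagonal covariances by ``lam``."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(M, list(C.species_order))


def eb_transform(tree: Phylogeny, a: float) -> PhyloCovariance:
    """Covariance under an exponentially decaying rate sigma2(t) = exp(a t).

    ``a <= 0`` (early burst / slowdown). The BM limit a = 0 returns
    ``phylo_covariance`` exactly.
    """
    if a > 0:
        raise ValueError("EB rate parameter a must be <= 0 (rate decay)")
    C = phylo_covariance(tree)
    if a == 0:
        return C
    M = np.expm1(a * C.matrix) / a
    return PhyloCovariance(M, C.species_order)


# ------------------------------------------------------------------ traits
def trait_vector(tree: Phylogeny, trait) -> np.ndarray:
    """Align a species-keyed trait (Series/Mapping) with tip label order."""
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, Mapping):
        missing = [lab for lab in tree.tip_labels if lab not in trait]
        if missing:
            raise KeyError(f"trait missing for species: {missing}")
        return np.asarray([float(trait[lab]) for lab in tree.tip_labels])
    x = np.asarray(trait, dtype=float)
    if x.shape[0] != tree.n_tips:
        raise ValueError("trait vector length does not match number of tips")
    return x


def trait_matrix(tree: Phylogeny, traits) -> np.ndarray:
    if isinstance(traits, pd.DataFrame):
        missing = [lab for lab in tree.tip_labels if lab not in traits.index]
        if missing:
            raise KeyError(f"traits missing for species: {missing}")
        return traits.loc[tree.tip_labels].to_numpy(dtype=float)
    X = np.asarray(traits, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != tree.n_tips:
        raise ValueError("trait matrix row count does not match number of tips")
    return X


# ------------------------------------------------------------------ contrasts
@dataclass
class ContrastSet:
    """Felsenstein standardized independent contrasts, one per internal node."""

    contrasts: np.ndarray
    variances: np.ndarray
    node_heights: np.ndarray  # time since root of each contrast's node
    nodes: np.ndarray

    def __len__(self) -> int:
        return len(self.contrasts)


def independent_contrasts(tree: Phylogeny, trait) -> ContrastSet:
    """Standardized contrasts via the pruning algorithm with branch extension.

    Node heights are reported as time elapsed from the root, so large heights
    are recent nodes.
    """
    x = trait_vector(tree, trait)
    n = tree.n_nodes
    val = np.zeros(n)
    val[: tree.n_tips] = x
    v = tree.edge_length.astype(float).copy()
    eps = 1e-12 * max(tree.height, 1.0)
    contrasts, variances, nodes = [], [], []
    for node in tree.postorder:
        if tree.is_tip(node):
            continue
        c1, c2 = tree.children[node]
        v1, v2 = max(v[c1], eps), max(v[c2], eps)
        contrasts.append((val[c1] - val[c2]) / np.sqrt(v1 + v2))
        variances.append(v1 + v2)
        nodes.append(node)
        val[node] = (val[c1] / v1 + val[c2] / v2) / (1 / v1 + 1 / v2)
        v[node] = v[node] + v1 * v2 / (v1 + v2)
    h = tree.node_heights
    return ContrastSet(
        np.asarray(contrasts),
        np.asarray(variances),
        h[np.asarray(nodes, dtype=np.int64)],
        np.asarray(nodes, dtype=np.int64),
    )


# ----------------------------------------------------------- ancestral states
def ancestral_states_ml(tree: Phylogeny, trait) -> np.ndarray:
    """ML (GLS) ancestral state estimates under Brownian motion.

    Maximizes the joint Gaussian likelihood of internal states given the tips,
    which reduces to a weighted graph-Laplacian linear system with edge weights
    1/branch length. Zero-length branches (e.g. resolved polytomies) are
    regularized with a tiny epsilon, which makes zero-length pendant pairs a
    weighted mean rather than a singularity.

    Returns states for all nodes (tips carry their observed values); index by
    node id. Use :func:`edge_interpolation` for along-branch interpolation.
    """
    x = trait_vector(tree, trait)
    n, nt = tree.n_nodes, tree.n_tips
    eps = 1e-8 * max(tree.height, 1.0)
    w = 1.0 / np.maximum(tree.edge_length, eps)  # weight of edge above node
    internal = [node for node in tree.postorder if not tree.is_tip(node)]
    pos = {node: i for i, node in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for node in internal:
        i = pos[node]
        for c in tree.children[node]:
            A[i, i] += w[c]
            if tree.is_tip(c):
                b[i] += w[c] * x[c]
            else:
                A[i, pos[c]] -= w[c]
        p = tree.parent[node]
        if p >= 0:
            A[i, i] += w[node]
            A[i, pos[p]] -= w[node]
    states = np.zeros(n)
    states[:nt] = x
    states[np.asarray(internal, dtype=np.int64)] = np.linalg.solve(A, b)
    return states


def edge_interpolation(tree: Phylogeny, states: np.ndarray, n_points: int = 10):
    """Linear-in-time interpolation of node states along each edge.

    Returns ``{child_node: (times, values)}`` with times measured from the
    root, emulating continuous trait maps painted on branches.
    """
    h = tree.node_heights
    out = {}
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        t = np.linspace(h[p], h[node], n_points)
        if h[node] > h[p]:
            frac = (t - h[p]) / (h[node] - h[p])
        else:
            frac = np.ones_like(t)
        out[node] = (t, states[p] + frac * (states[node] - states[p]))
    return out


# -------------------------------------------------------------------- pruning
def prune_to_subset(tree: Phylogeny, labels) -> Phylogeny:
    """Induced subtree on ``labels``: degree-2 nodes suppressed, lengths summed."""
    labels = list(labels)
    unknown = [lab for lab in labels if lab not in tree.tip_index]
    if unknown:
        raise KeyError(f"labels not in tree: {unknown}")
    if len(labels) < 2:
        raise ValueError("need at least 2 labels to prune to")
    keep = set(labels)

    def rec(node: int):
        if tree.is_tip(node):
            lab = tree.tip_labels[node]
            if lab in keep:
                return (lab, float(tree.edge_length[node]), None)
            return None
        kids = [rec(c) for c in tree.children[node]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            lab, length, gk = kids[0]
            return (lab, length + float(tree.edge_length[node]), gk)
        return (None, float(tree.edge_length[node]), kids)

    nested = rec(tree.root)
    label, length, kids = nested
    if kids is not None:
        nested = (label, 0.0, kids)  # new root carries no stem
    else:
        raise ValueError("pruning left fewer than 2 tips")
    return Phylogeny.from_nested(nested)
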