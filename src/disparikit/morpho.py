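"""Geometric morphometrics of 2D landmark data and linear-trait preprocessing.

Implements generalized Procrustes analysis (translate to the origin, scale to
unit centroid size, optimally rotate without reflection until the consensus
stabilizes), species mean shapes, tangent-space PCA, a permutation test for
allometry, and log-log residual size correction of linear measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "AlignedShapes",
    "ShapePCA",
    "read_landmarks",
    "write_landmarks",
    "centroid_size",
    "gpa",
    "species_mean_shapes",
    "tangent_pca",
    "allometry_test",
    "size_correct",
    "femur_ratio",
]


@dataclass
class LandmarkSet:
    """Specimen-indexed landmark configurations with species labels.

    ``coords`` has shape (n_specimens, k_landmarks, 2); ``scale`` is an
    optional per-specimen digitization scale factor.
    """

    specimen_ids: list[str]
    species: list[str]
    coords: np.ndarray
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_specimens, k, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        n = self.coords.shape[0]
        if len(self.specimen_ids) != n or len(self.species) != n:
            raise ValueError("specimen_ids/species lengths do not match coords")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]


def read_landmarks(path) -> LandmarkSet:
    """Parse the plain-text landmark dialect.

    Blocks of ``ID=<specimen> SPECIES=<label> SCALE=<float>`` followed by one
    ``x y`` line per landmark, separated by blank lines.
    """
    ids, species, coords, scales = [], [], [], []
    block_pts: list[list[float]] = []

    def flush():
        if block_pts:
            coords.append(np.asarray(block_pts, dtype=float))
            block_pts.clear()

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("ID="):
                flush()
                fields = dict(tok.split("=", 1) for tok in line.split())
                ids.append(fields["ID"])
                species.append(fields["SPECIES"])
                scales.append(float(fields.get("SCALE", 1.0)))
            else:
                x, y = line.split()
                block_pts.append([float(x), float(y)])
    flush()
    arr = np.asarray(coords)
    if arr.ndim != 3:
        raise ValueError("inconsistent landmark counts across specimens")
    return LandmarkSet(ids, species, arr, np.asarray(scales))


def write_landmarks(lms: LandmarkSet, path) -> None:
    scale = lms.scale if lms.scale is not None else np.ones(lms.n_specimens)
    with open(path, "w") as fh:
        for i in range(lms.n_specimens):
            fh.write(f"ID={lms.specimen_ids[i]} SPECIES={lms.species[i]} "
                     f"SCALE={format(scale[i], '.17g')}\n")
            for x, y in lms.coords[i]:
                fh.write(f"{format(x, '.17g')} {format(y, '.17g')}\n")
            fh.write("\n")


# ------------------------------------------------------------------ geometry
def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    X = np.asarray(config, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("configuration must be a (k>=3, d) array")
    dev = X - X.mean(axis=0)
    cs = float(np.sqrt((dev ** 2).sum()))
    if cs == 0:
        raise ValueError("degenerate configuration: all landmarks identical")
    return cs


def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (no reflection) minimizing ||X R^T - target||."""
    H = X.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return (U @ D @ Vt).T  # apply as X @ R.T


@dataclass
class AlignedShapes:
    """GPA output: unit-centroid-size aligned configurations and consensus."""

    specimen_ids: list[str]
    species: list[str]
    aligned: np.ndarray  # (n, k, 2)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # original sizes
    n_iterations: int = 0


def gpa(lms: LandmarkSet, tol: float = 1e-10, max_iter: int = 1000) -> AlignedShapes:
    """Generalized Procrustes analysis.

    Each configuration is translated to the origin, scaled to unit centroid
    size, and rotated to the running consensus; iterate until the consensus
    moves less than ``tol``.
    """
    if lms.n_specimens < 2:
        raise ValueError("GPA needs at least 2 specimens")
    X = lms.coords - lms.coords.mean(axis=1, keepdims=True)
    cs = np.sqrt((X ** 2).sum(axis=(1, 2)))
    if np.any(cs == 0):
        raise ValueError("degenerate configuration in input")
    X = X / cs[:, None, None]
    consensus = X[0].copy()
    for it in range(max_iter):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus).T
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt((new ** 2).sum())
        delta = np.sqrt(((new - consensus) ** 2).sum())
        consensus = new
        if delta < tol:
            return AlignedShapes(list(lms.specimen_ids), list(lms.species),
                                 X, consensus, cs, it + 1)
    raise RuntimeError(
        f"GPA did not converge in {max_iter} iterations (last delta {delta:.3e})"
    )


def species_mean_shapes(aligned: AlignedShapes) -> tuple[pd.DataFrame, pd.Series]:
    """Coordinatewise mean aligned shape and mean centroid size per species.

    Returns a (species x 2k) DataFrame of flattened coordinates (columns
    x1, y1, x2, y2, ...) and a Series of mean centroid sizes.
    """
    species = np.asarray(aligned.species)
    labs = sorted(set(aligned.species))
    k = aligned.aligned.shape[1]
    flat = aligned.aligned.reshape(len(species), 2 * k)
    rows, sizes = [], []
    for lab in labs:
        mask = species == lab
        if not mask.any():
            raise ValueError(f"species {lab} has no specimens")
        rows.append(flat[mask].mean(axis=0))
        sizes.append(aligned.centroid_sizes[mask].mean())
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    means = pd.DataFrame(np.asarray(rows), index=labs, columns=cols)
    means.index.name = "species"
    return means, pd.Series(sizes, index=labs, name="centroid_size")


@dataclass
class ShapePCA:
    """Tangent-space principal components of species mean shapes."""

    scores: pd.DataFrame
    loadings: np.ndarray  # (2k, n_axes) orthonormal columns
    var_prop: np.ndarray
    eigenvalues: np.ndarray
    degenerate: bool = False


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic axis orientation: largest-|loading| entry positive."""
    vecs = vecs.copy()
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


def tangent_pca(species_shapes: pd.DataFrame) -> ShapePCA:
    """Covariance PCA of flattened aligned coordinates (tangent space)."""
    X = species_shapes.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("tangent PCA needs at least 3 species")
    Xc = X - X.mean(axis=0)
    total = (Xc ** 2).sum() / (n - 1)
    if total <= 1e-300:
        return ShapePCA(
            scores=pd.DataFrame(np.zeros((n, 1)), index=species_shapes.index,
                                columns=["PC1"]),
            loadings=np.zeros((X.shape[1], 1)),
            var_prop=np.zeros(1), eigenvalues=np.zeros(1), degenerate=True,
        )
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    keep = eig > 1e-12 * eig[0]
    eig, V = eig[keep], _fix_signs(Vt[keep].T)
    scores = Xc @ V
    cols = [f"PC{i + 1}" for i in range(V.shape[1])]
    return ShapePCA(
        scores=pd.DataFrame(scores, index=species_shapes.index, columns=cols),
        loadings=V, var_prop=eig / eig.sum(), eigenvalues=eig,
    )


def allometry_test(shapes: pd.DataFrame, centroid_sizes: pd.Series,
                   n_perm: int = 999, seed: int | None = 0,
                   rng: np.random.Generator | None = None) -> dict:
    """Permutation test of shape-on-log(size) multivariate regression.

    The statistic is the model sum of squares of the regression of every
    shape coordinate on log centroid size; size labels are permuted.
    p = (#{perm >= observed} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Y = shapes.to_numpy(dtype=float)
    x = np.log(centroid_sizes.loc[shapes.index].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("centroid size is constant; allometry test undefined")
    if rng is None:
        rng = np.random.default_rng(seed)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sxx = (xc ** 2).sum()

    def ss_model(xv):
        beta = xv @ Yc / sxx
        return float((beta ** 2).sum() * sxx)

    obs = ss_model(xc)
    tol = 1e-12 * (1.0 + abs(obs))  # count numerical ties as exceedances
    count = 0
    for _ in range(n_perm):
        count += ss_model(rng.permutation(xc)) >= obs - tol
    return {"statistic": obs, "p_value": (count + 1) / (n_perm + 1),
            "n_perm": n_perm}


# ------------------------------------------------------------- linear traits
def size_correct(trait: pd.Series, body_length: pd.Series) -> pd.Series:
    """Relative trait: residuals of OLS log(trait) ~ log(body length)."""
    trait, body_length = trait.align(body_length, join="inner")
    if (trait <= 0).any() or (body_length <= 0).any():
        raise ValueError("trait and body length must be positive")
    y = np.log(trait.to_numpy(dtype=float))
    x = np.log(body_length.to_numpy(dtype=float))
    xc = x - x.mean()
    beta = float(xc @ (y - y.mean()) / (xc ** 2).sum())
    resid = y - y.mean() - beta * xc
    return pd.Series(resid, index=trait.index, name=f"rel_{trait.name or 'trait'}")


def femur_ratio(width: pd.Series, length: pd.Series) -> pd.Series:
    """Elementwise femur width/length ratio."""
    width, length = width.align(length, join="inner")
    if (length <= 0).any():
        raise ValueError("femur length must be positive")
    if (width <= 0).any():
        raise ValueError("femur width must be positive")
    out = width / length
    out.name = "femur_ratio"
    return out
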