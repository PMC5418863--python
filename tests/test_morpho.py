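"""Geometric morphometrics and linear-trait preprocessing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from disparikit.morpho import (
    LandmarkSet,
    allometry_test,
    centroid_size,
    femur_ratio,
    gpa,
    read_landmarks,
    size_correct,
    species_mean_shapes,
    tangent_pca,
    write_landmarks,
)


def _random_landmarks(rng, n_spec=6, k=8, n_species=3, noise=0.05):
    base = rng.normal(size=(k, 2))
    coords, ids, species = [], [], []
    for i in range(n_spec):
        coords.append(base + rng.normal(0, noise, size=(k, 2)))
        ids.append(f"spec{i}")
        species.append(f"sp{i % n_species}")
    return LandmarkSet(ids, species, np.asarray(coords))


def _similarity(rng, cfg):
    ang = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return rng.uniform(0.5, 2.0) * cfg @ R.T + rng.normal(0, 3, size=2)


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(sq) == pytest.approx(np.sqrt(2.0))

    def test_homogeneous_scaling(self, rng):
        cfg = rng.normal(size=(14, 2))
        assert centroid_size(3.7 * cfg) == pytest.approx(3.7 * centroid_size(cfg))

    def test_equilateral_triangle(self):
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        assert centroid_size(tri) == pytest.approx(1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            centroid_size(np.ones((5, 2)))


class TestGPA:
    def test_identical_configs_zero_distance(self, rng):
        cfg = rng.normal(size=(10, 2))
        lms = LandmarkSet(["a", "b"], ["s", "s"], np.array([cfg, cfg]))
        al = gpa(lms)
        assert np.abs(al.aligned[0] - al.aligned[1]).max() < 1e-12

    def test_similarity_invariance(self, rng):
        """A transformed copy aligns exactly onto the original."""
        cfg = rng.normal(size=(14, 2))
        lms = LandmarkSet(["a", "b"], ["s", "s"],
                          np.array([cfg, _similarity(rng, cfg)]))
        al = gpa(lms)
        assert np.abs(al.aligned[0] - al.aligned[1]).max() < 1e-9

    def test_invariant_to_global_similarity(self, rng):
        """Transforming every input specimen leaves the GPA output unchanged."""
        lms = _random_landmarks(rng)
        al1 = gpa(lms)
        coords2 = np.array([_similarity(rng, c) for c in lms.coords])
        al2 = gpa(LandmarkSet(lms.specimen_ids, lms.species, coords2))
        # align the two consensuses before comparing (rotation gauge freedom)
        H = al2.consensus.T @ al1.consensus
        U, _, Vt = np.linalg.svd(H)
        D = np.diag([1, np.sign(np.linalg.det(U @ Vt))])
        R = (U @ D @ Vt)
        assert np.abs(al2.aligned @ R - al1.aligned).max() < 1e-9

    def test_consensus_recovers_true_shape(self, rng):
        """Consensus of noisy copies converges at the noise/sqrt(n) rate."""
        tri = np.array([[0, 0], [1, 0], [0.5, 0.9]])
        tri = tri - tri.mean(axis=0)
        tri /= centroid_size(tri)
        noise = 0.01
        errs = []
        for _ in range(100):
            coords = np.array([tri + rng.normal(0, noise, size=(3, 2))
                               for _ in range(3)])
            al = gpa(LandmarkSet(list("abc"), list("sss"), coords))
            H = al.consensus.T @ tri
            U, _, Vt = np.linalg.svd(H)
            D = np.diag([1, np.sign(np.linalg.det(U @ Vt))])
            errs.append(np.sqrt(((al.consensus @ (U @ D @ Vt) - tri) ** 2).sum()))
        assert np.mean(errs) < noise / np.sqrt(3) * 2.0

    def test_needs_two_specimens(self, rng):
        with pytest.raises(ValueError):
            gpa(LandmarkSet(["a"], ["s"], rng.normal(size=(1, 5, 2))))


class TestSpeciesMeans:
    def test_single_specimen_identity(self, rng):
        lms = _random_landmarks(rng, n_spec=3, n_species=3)
        al = gpa(lms)
        means, cs = species_mean_shapes(al)
        for i, sp in enumerate(al.species):
            np.testing.assert_allclose(means.loc[sp].to_numpy(),
                                       al.aligned[i].ravel())

    def test_matches_direct_average(self, rng):
        lms = _random_landmarks(rng, n_spec=9, n_species=3)
        al = gpa(lms)
        means, cs = species_mean_shapes(al)
        sp = np.asarray(al.species)
        for lab in means.index:
            np.testing.assert_allclose(
                means.loc[lab].to_numpy(),
                al.aligned[sp == lab].mean(axis=0).ravel())
            assert cs[lab] == pytest.approx(al.centroid_sizes[sp == lab].mean())


class TestTangentPCA:
    def test_degenerate_flagged(self):
        X = pd.DataFrame(np.ones((4, 6)))
        res = tangent_pca(X)
        assert res.degenerate

    def test_rank_one_variation(self, rng):
        direction = rng.normal(size=10)
        t = rng.normal(size=8)
        X = pd.DataFrame(np.outer(t, direction))
        res = tangent_pca(X)
        assert res.var_prop[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 6)))
        res = tangent_pca(X)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        S = Xc.T @ Xc / 9
        w, v = np.linalg.eigh(S)
        w = w[::-1][: len(res.eigenvalues)]
        np.testing.assert_allclose(res.eigenvalues, w, rtol=1e-8)
        total = (Xc ** 2).sum() / 9
        assert res.eigenvalues.sum() == pytest.approx(total)

    def test_needs_three_species(self):
        with pytest.raises(ValueError):
            tangent_pca(pd.DataFrame(np.eye(2)))


class TestAllometry:
    def test_identical_shapes_p_one(self, rng):
        X = pd.DataFrame(np.tile(rng.normal(size=6), (8, 1)))
        cs = pd.Series(np.exp(rng.normal(size=8)), index=X.index)
        res = allometry_test(X, cs, n_perm=99, seed=0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_detects_size_deformation(self, rng):
        n = 30
        size = pd.Series(np.exp(rng.normal(size=n)))
        direction = rng.normal(size=8)
        X = pd.DataFrame(np.outer(np.log(size), direction)
                         + 0.01 * rng.normal(size=(n, 8)))
        res = allometry_test(X, size, n_perm=999, seed=1)
        assert res["p_value"] <= 0.01

    def test_null_p_uniform(self, rng):
        """p-values under independence are approximately Uniform(0,1)."""
        pvals = []
        for _ in range(200):
            X = pd.DataFrame(rng.normal(size=(12, 6)))
            cs = pd.Series(np.exp(rng.normal(size=12)), index=X.index)
            pvals.append(allometry_test(X, cs, n_perm=99, rng=rng)["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_size_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError):
            allometry_test(X, pd.Series(np.ones(5), index=X.index))


class TestSizeCorrection:
    def test_perfect_allometry_zero_residuals(self):
        body = pd.Series([10.0, 20.0, 30.0, 40.0], index=list("abcd"))
        trait = 0.3 * body
        res = size_correct(trait, body)
        np.testing.assert_allclose(res.to_numpy(), 0.0, atol=1e-12)

    def test_size_independent_trait(self, rng):
        body = pd.Series(np.exp(rng.normal(size=50)))
        trait = pd.Series(np.exp(rng.normal(size=50)))
        res = size_correct(trait, body)
        logt = np.log(trait)
        # residuals nearly the centered log trait (slope ~ 0)
        assert np.corrcoef(res, logt - logt.mean())[0, 1] > 0.95

    def test_recovers_constructed_residuals(self, rng):
        body = pd.Series(np.exp(rng.normal(size=40)))
        resid_true = rng.normal(size=40)
        resid_true -= resid_true.mean()
        x = np.log(body.to_numpy())
        resid_true -= (resid_true @ (x - x.mean())) / ((x - x.mean()) ** 2).sum() * (x - x.mean())
        trait = pd.Series(np.exp(1.2 + 0.8 * x + resid_true), index=body.index)
        res = size_correct(trait, body)
        np.testing.assert_allclose(res.to_numpy(), resid_true, atol=1e-10)

    def test_invariants(self, rng):
        body = pd.Series(np.exp(rng.normal(size=30)))
        trait = pd.Series(np.exp(rng.normal(size=30)))
        res = size_correct(trait, body)
        assert abs(res.sum()) < 1e-10
        x = np.log(body.to_numpy())
        assert abs(res.to_numpy() @ (x - x.mean())) < 1e-9

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            size_correct(pd.Series([1.0, -2.0]), pd.Series([1.0, 2.0]))


class TestFemurRatio:
    def test_examples(self):
        w = pd.Series([1.0, 2.0], index=["a", "b"])
        l = pd.Series([2.0, 2.0], index=["a", "b"])
        r = femur_ratio(w, l)
        assert r["a"] == pytest.approx(0.5)
        assert r["b"] == pytest.approx(1.0)

    def test_vectorized_matches_loop(self, rng):
        w = pd.Series(rng.uniform(0.5, 2, 70))
        l = pd.Series(rng.uniform(1, 4, 70))
        r = femur_ratio(w, l)
        for i in range(70):
            assert r.iloc[i] == pytest.approx(w.iloc[i] / l.iloc[i])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            femur_ratio(pd.Series([1.0]), pd.Series([0.0]))


class TestLandmarkIO:
    def test_round_trip(self, tmp_path, rng):
        lms = _random_landmarks(rng)
        path = tmp_path / "lms.txt"
        write_landmarks(lms, path)
        back = read_landmarks(path)
        assert back.specimen_ids == lms.specimen_ids
        assert back.species == lms.species
        np.testing.assert_allclose(back.coords, lms.coords, rtol=1e-12)
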