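"""Trait-evolution model fits, AICc, stochastic mapping, model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from disparikit.models import (
    aicc,
    bm_loglik,
    compare_models,
    eb_loglik,
    fit_bm,
    fit_eb,
    fit_mk,
    fit_ou1,
    fit_oumv,
    ou1_loglik,
    oumv_loglik,
    stochastic_maps,
)
from disparikit.simulate import (
    SimulationConfig,
    simulate_mk,
    simulate_trait,
    simulate_yule,
    uniform_history,
)
from disparikit.tree import phylo_covariance, read_newick


def history_with_tip_paint(tree, recent_state="ground", old_state="plant",
                           switch_frac=0.5):
    """Regime history switching every lineage at a fixed absolute time."""
    hist = uniform_history(tree, old_state)
    h = tree.node_heights
    t_sw = switch_frac * tree.height
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        t0, t1 = h[p], h[node]
        if t1 <= t_sw:
            hist.segments[node] = [(t0, t1, old_state)]
        elif t0 >= t_sw:
            hist.segments[node] = [(t0, t1, recent_state)]
        else:
            hist.segments[node] = [(t0, t_sw, old_state),
                                   (t_sw, t1, recent_state)]
    hist.tip_states[:] = recent_state
    return hist


class TestAicc:
    def test_arithmetic(self):
        assert aicc(0.0, 2, 70) == pytest.approx(4.0 + 12.0 / 67.0)
        assert aicc(-10.0, 3, 70) == pytest.approx(26.0 + 24.0 / 66.0)

    def test_large_n_limit(self):
        assert aicc(-5.0, 4, 10 ** 5) == pytest.approx(10.0 + 8.0, abs=1e-3)

    def test_increasing_in_k(self):
        vals = [aicc(-3.0, k, 50) for k in range(1, 6)]
        assert np.all(np.diff(vals) > 0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)


class TestBm:
    def test_two_tip_closed_form(self):
        tree = read_newick("(A:1,B:1);")
        tree3 = read_newick("((A:1,B:1):0.0001,C:1.0001);")
        fit = fit_bm(tree3, {"A": 0.0, "B": 2.0, "C": 1.0})
        assert fit.z0 == pytest.approx(1.0, abs=1e-3)
        # genuine 2-tip closed form via the likelihood function directly
        ll = bm_loglik(tree, {"A": 0.0, "B": 2.0}, sigma2=1.0, z0=1.0)
        want = stats.multivariate_normal([1.0, 1.0], np.eye(2)).logpdf([0.0, 2.0])
        assert ll == pytest.approx(want, abs=1e-10)

    def test_constant_trait_degenerate(self, yule10):
        fit = fit_bm(yule10, dict.fromkeys(yule10.tip_labels, 2.0))
        assert fit.degenerate
        assert fit.sigma2_scalar == 0.0

    def test_loglik_matches_mvn(self, yule10, rng):
        x = pd.Series(rng.normal(size=10), index=yule10.tip_labels)
        fit = fit_bm(yule10, x)
        C = phylo_covariance(yule10).matrix
        want = stats.multivariate_normal(
            np.full(10, fit.z0), fit.sigma2_scalar * C).logpdf(
                x.loc[yule10.tip_labels].to_numpy())
        assert fit.loglik == pytest.approx(want, abs=1e-8)


class TestEb:
    def test_a_zero_equals_bm(self, yule10, rng):
        x = pd.Series(rng.normal(size=10), index=yule10.tip_labels)
        bm = fit_bm(yule10, x)
        ll = eb_loglik(yule10, x, bm.sigma2_scalar, 0.0, bm.z0)
        assert ll == pytest.approx(bm.loglik, abs=1e-8)

    def test_nests_bm(self, yule70, rng):
        for _ in range(10):
            x = simulate_trait(yule70,
                               SimulationConfig(model="BM", sigma2=1.0),
                               rng=rng)
            eb = fit_eb(yule70, x)
            bm = fit_bm(yule70, x)
            assert eb.loglik >= bm.loglik - 1e-6

    def test_recovers_decay_sign(self, rng):
        tree = simulate_yule(70, 1.0, seed=21).rescale(1.0)
        hits = 0
        n_rep = 30
        for _ in range(n_rep):
            x = simulate_trait(tree, SimulationConfig(model="EB", sigma2=1.0,
                                                      eb_rate=-2.0), rng=rng)
            hits += fit_eb(tree, x).eb_rate < -1e-6
        assert hits >= 0.8 * n_rep

    def test_bm_preferred_on_bm_data(self, yule70, rng):
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            x = simulate_trait(yule70,
                               SimulationConfig(model="BM", sigma2=1.0),
                               rng=rng)
            wins += fit_bm(yule70, x).aicc < fit_eb(yule70, x).aicc
        assert wins > n_rep / 2


class TestOu1:
    def test_continuity_at_bm_limit(self, yule10, rng):
        x = pd.Series(rng.normal(size=10), index=yule10.tip_labels)
        bm = fit_bm(yule10, x)
        ll = ou1_loglik(yule10, x, bm.sigma2_scalar, 1e-9, bm.z0)
        assert abs(ll - bm.loglik) < 1e-4

    def test_nests_bm(self, yule70, rng):
        for _ in range(10):
            x = simulate_trait(yule70,
                               SimulationConfig(model="OU1", sigma2=1.0,
                                                alpha=2.0, theta=1.0, z0=1.0),
                               rng=rng)
            assert fit_ou1(yule70, x).loglik >= fit_bm(yule70, x).loglik - 1e-6

    def test_theta_recovery(self, rng):
        tree = simulate_yule(70, 1.0, seed=33).rescale(1.0)
        cfg = SimulationConfig(model="OU1", sigma2=1.0, alpha=2.0, theta=5.0,
                               z0=5.0)
        thetas = [fit_ou1(tree, simulate_trait(tree, cfg, rng=rng)).theta[""]
                  for _ in range(30)]
        assert np.median(thetas) == pytest.approx(5.0, rel=0.1)

    def test_loglik_matches_mvn(self, yule10, rng):
        x = pd.Series(rng.normal(size=10), index=yule10.tip_labels)
        fit = fit_ou1(yule10, x)
        ll = ou1_loglik(yule10, x, fit.sigma2_scalar, fit.alpha, fit.theta[""])
        assert ll == pytest.approx(fit.loglik, abs=1e-8)


class TestOumv:
    def test_single_switch_matches_segmentwise_oracle(self):
        """Piecewise OU moments integrated segment by segment, by hand."""
        tree = read_newick(
            "(((A:0.2,B:0.2):0.3,(C:0.1,D:0.1):0.4):0.5,(E:0.3,F:0.3):0.7);")
        hist = history_with_tip_paint(tree, switch_frac=0.6)
        alpha, s2 = 1.7, {"plant": 0.8, "ground": 2.1}
        th = {"plant": -1.0, "ground": 2.0}
        trait = {"A": 0.3, "B": -0.2, "C": 1.4, "D": 0.9, "E": -1.1, "F": 2.2}
        got = oumv_loglik(tree, trait, hist, alpha, s2, th)

        # oracle: explicit per-tip path segments, scalar quadrature
        from scipy.integrate import quad
        h = tree.node_heights
        T = tree.height

        def path_segments(tip):
            segs, node = [], tip
            while tree.parent[node] >= 0:
                segs = list(hist.segments[node]) + segs
                node = tree.parent[node]
            return segs

        labels = tree.tip_labels
        n = len(labels)
        mean = np.empty(n)
        cov = np.empty((n, n))
        paths = {i: path_segments(i) for i in range(n)}
        for i in range(n):
            m = th["plant"] * np.exp(-alpha * T)  # root at plant optimum
            for (t0, t1, st) in paths[i]:
                m += th[st] * quad(
                    lambda u: alpha * np.exp(-alpha * (T - u)), t0, t1)[0]
            mean[i] = m
        C = phylo_covariance(tree).matrix
        for i in range(n):
            for j in range(n):
                s_ij = C[i, j]
                acc = 0.0
                for (t0, t1, st) in paths[i]:
                    a, b = t0, min(t1, s_ij)
                    if b > a:
                        acc += s2[st] * quad(
                            lambda u: np.exp(-2 * alpha * (T - u)), a, b)[0]
                cov[i, j] = acc
        want = stats.multivariate_normal(mean, cov).logpdf(
            [trait[lab] for lab in labels])
        assert got == pytest.approx(want, abs=1e-6)

    def test_nests_ou1(self, yule70, rng):
        hist = history_with_tip_paint(yule70)
        for _ in range(5):
            x = simulate_trait(yule70,
                               SimulationConfig(model="OU1", sigma2=1.0,
                                                alpha=2.0, theta=0.0),
                               rng=rng)
            f2 = fit_oumv(yule70, x, hist)
            f1 = fit_ou1(yule70, x)
            assert f2.loglik >= f1.loglik - 1e-6

    def test_parsimony_prefers_ou1_when_true(self, yule70, rng):
        hist = history_with_tip_paint(yule70)
        cfg = SimulationConfig(model="OU1", sigma2=1.0, alpha=2.0, theta=0.0)
        wins = 0
        n_rep = 30
        for _ in range(n_rep):
            x = simulate_trait(yule70, cfg, rng=rng)
            wins += fit_ou1(yule70, x).aicc < fit_oumv(yule70, x, hist).aicc
        assert wins > n_rep / 2

    def test_absent_regime_rejected(self, yule70, rng):
        hist = uniform_history(yule70, "plant")
        x = pd.Series(rng.normal(size=70), index=yule70.tip_labels)
        with pytest.raises(ValueError, match="ground"):
            fit_oumv(yule70, x, hist)

    def test_loglik_matches_mvn_at_fit(self, yule70, rng):
        hist = history_with_tip_paint(yule70)
        cfg = SimulationConfig(model="OUMV", alpha=3.0,
                               sigma2={"plant": 1.0, "ground": 2.0},
                               theta={"plant": -1.0, "ground": 1.0}, z0=-1.0)
        x = simulate_trait(yule70, cfg, regimes=hist, rng=rng)
        fit = fit_oumv(yule70, x, hist)
        ll = oumv_loglik(yule70, x, hist, fit.alpha, fit.sigma2, fit.theta)
        assert ll == pytest.approx(fit.loglik, abs=1e-6)


class TestStochasticMaps:
    def test_invariant_tips_rejected(self, yule10):
        tips = pd.Series("plant", index=yule10.tip_labels)
        with pytest.raises(ValueError):
            stochastic_maps(yule10, tips, n_maps=2)

    def test_maps_reproduce_tip_states(self, yule70):
        Q = np.array([[-2.0, 2.0], [2.0, -2.0]])
        hist = simulate_mk(yule70, Q, "ground", seed=11)
        maps = stochastic_maps(yule70, hist.tip_states, n_maps=20, seed=4)
        for m in maps:
            pd.testing.assert_series_equal(m.tip_states, hist.tip_states)
            m.validate(yule70)

    def test_segregated_clades_force_a_change(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tips = pd.Series({"A": "plant", "B": "plant",
                          "C": "ground", "D": "ground"})
        maps = stochastic_maps(tree, tips, n_maps=30, seed=0)
        for m in maps:
            assert m.n_changes() >= 1

    def test_change_count_tracks_generating_process(self, yule70):
        """Mean mapped changes within 25% of the generating expectation."""
        q = 2.0
        Q = np.array([[-q, q], [q, -q]])
        total_len = yule70.edge_length.sum()
        rng = np.random.default_rng(17)
        hist = simulate_mk(yule70, Q, "ground", rng=rng)
        while hist.tip_states.nunique() < 2:
            hist = simulate_mk(yule70, Q, "ground", rng=rng)
        # map under the generating Q so the check isolates the path sampler
        maps = stochastic_maps(yule70, hist.tip_states, n_maps=500, seed=1,
                               q_matrix=Q)
        mean_changes = np.mean([m.n_changes() for m in maps])
        assert mean_changes == pytest.approx(q * total_len, rel=0.25)

    def test_fit_mk_recovers_rate_scale(self, yule70):
        q = 2.0
        Q = np.array([[-q, q], [q, -q]])
        hist = simulate_mk(yule70, Q, "ground", seed=2)
        Qhat = fit_mk(yule70, hist.tip_states)
        assert 0.2 * q < Qhat[0, 1] < 5 * q


class TestCompareModels:
    def test_min_delta_zero_and_table_shape(self, yule70, rng):
        Q = np.array([[-2.0, 2.0], [2.0, -2.0]])
        hist = simulate_mk(yule70, Q, "ground", seed=5)
        x = simulate_trait(yule70, SimulationConfig(model="BM", sigma2=1.0),
                           rng=rng)
        comp = compare_models(yule70, x, hist.tip_states, n_maps=10, seed=2)
        assert comp.table["dAICc"].min() == 0.0
        assert list(comp.table.index) == ["BM", "EB", "OU1", "OUMV"]
        assert len(comp.oumv_aiccs) == 10
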