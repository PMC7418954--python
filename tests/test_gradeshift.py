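import numpy as np
import pandas as pd
import pytest

from phylarynx import (
    detect_shifts,
    gls_fit,
    grade_magnitude,
    loglik_mvn,
    ou_regime_fit,
    pancova,
    read_tree,
    shift_support,
    simulate_bm,
    simulate_ou_shifts,
    simulate_tree,
    snr,
    vcv_bm,
)
from phylarynx.gradeshift import _painting_from_shifts


def ou_moments_by_recursion(tree, node_regime, theta, alpha, sigma2):
    """Independent oracle: joint tip mean/covariance by per-edge
    linear-Gaussian propagation (child = decayed parent + pull + noise)."""
    n_nodes = tree.n_nodes
    mean = np.zeros(n_nodes)
    cov = np.zeros((n_nodes, n_nodes))
    mean[0] = theta[0]  # root pinned to background optimum
    for v in tree.preorder[1:]:
        p = tree.parent[v]
        b = tree.blen[v]
        th = theta[node_regime[v]]
        e = np.exp(-alpha * b)
        mean[v] = th + (mean[p] - th) * e
        cov[v, :] = e * cov[p, :]
        cov[:, v] = cov[v, :]
        cov[v, v] = e**2 * cov[p, p] + sigma2 * (1 - e**2) / (2 * alpha)
    tips = tree.tip_ids
    return mean[tips], cov[np.ix_(tips, tips)]


class TestPancova:
    @pytest.fixture
    def grade_data(self, tree55):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(55)
        groups = ["A" if l.startswith("P") else "B" for l in tree55.tip_labels]
        y = 2.0 * x + np.where(np.array(groups) == "A", 1.0, 0.0)
        y = y + 0.1 * rng.standard_normal(55)
        return x, y, groups

    def test_detects_injected_intercept_offset(self, tree55, grade_data):
        x, y, groups = grade_data
        res = pancova(y, x, groups, tree55, hypothesis="intercepts")
        assert res.P < 1e-6
        assert res.df_num == 1

    def test_no_slope_difference_detected(self, tree55, grade_data):
        x, y, groups = grade_data
        res = pancova(y, x, groups, tree55, hypothesis="slopes")
        assert res.P > 0.01

    def test_identical_nested_models_raise(self, tree55, grade_data):
        x, y, groups = grade_data
        with pytest.raises(ValueError):
            pancova(y, x, ["A"] * 55, tree55)

    def test_f_nonnegative_and_df(self, tree55, grade_data):
        x, y, groups = grade_data
        res = pancova(y, x, groups, tree55, hypothesis="slopes")
        assert res.F >= 0
        assert res.df_den == 55 - res.model_full.p


class TestOuRegimeFit:
    def test_single_regime_bm_limit(self, tree55):
        """At alpha pinned to ~0 the one-regime OU collapses onto Brownian
        motion with the background optimum as the root state."""
        y = simulate_bm(tree55, 0.01, 0.0, seed=17)
        a0 = 1e-10 / tree55.depth
        m = ou_regime_fit(y, tree55, (), alpha_bounds=(a0, a0 * 1.0000001))
        V = vcv_bm(tree55)
        fit = gls_fit(y, np.ones((55, 1)), V, names=["root"])
        assert m.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_two_tip_stationarity_limit(self):
        t = read_tree("(A:1.0,B:1.0);")
        y = np.array([3.0, -2.0])
        # shift on tip A's edge; background covers tip B and the root
        ia = int(t.tip_ids[t.tip_labels.index("A")])
        pos_a = t.tip_labels.index("A")
        pos_b = 1 - pos_a
        m = ou_regime_fit(y, t, (ia,), alpha_bounds=(50.0, 500.0))
        # with huge alpha each optimum collapses onto its tip's value
        assert m.theta[1] == pytest.approx(y[pos_a], abs=1e-3)
        assert m.theta[0] == pytest.approx(y[pos_b], abs=1e-3)

    def test_strong_two_regime_theta_ordering(self, tree55):
        edge = next(
            v for v in range(1, tree55.n_nodes) if 5 <= len(tree55.tips_below(v)) <= 8
        )
        ok = 0
        reps = 20
        for i in range(reps):
            y = simulate_ou_shifts(
                tree55, (edge,), alpha=0.1, sigma2=0.02, theta=[0.0, 5 * np.sqrt(0.1)],
                seed=900 + i,
            )
            m = ou_regime_fit(y, tree55, (edge,))
            ok += m.theta[1] > m.theta[0]
        assert ok == reps

    def test_hansen_loglik_matches_recursion_oracle(self, tree55):
        edge = next(
            v for v in range(1, tree55.n_nodes) if 4 <= len(tree55.tips_below(v)) <= 10
        )
        y = simulate_ou_shifts(
            tree55, (edge,), alpha=0.05, sigma2=0.01, theta=[0.0, 1.5], seed=55
        )
        m = ou_regime_fit(y, tree55, (edge,))
        painting = _painting_from_shifts(tree55, (edge,))
        mean, cov = ou_moments_by_recursion(
            tree55, painting, m.theta, m.alpha, m.sigma2
        )
        assert m.loglik == pytest.approx(loglik_mvn(y, mean, cov), abs=1e-6)
        assert np.allclose(m.tip_expectations(), mean, atol=1e-9)
        assert np.allclose(m.tip_covariance(), cov, atol=1e-9)

    def test_empty_regime_raises(self, tree55):
        painting = np.zeros(tree55.n_nodes, dtype=int)
        painting[0] = 0
        # declare a regime 1 that paints no tip edge: pick an internal node
        internal = next(
            v for v in range(1, tree55.n_nodes) if not tree55.is_tip[v]
        )
        p = painting.copy()
        p[internal] = 1
        # repaint its children back to 0 so no tip carries regime 1
        for c in tree55.children[internal]:
            p[c] = 0
        with pytest.raises(ValueError, match="no tips"):
            ou_regime_fit(np.zeros(55), tree55, p)


class TestDetectShifts:
    def test_deterministic_given_data(self, tree55):
        y = simulate_bm(tree55, 0.01, 0.0, seed=77)
        m1 = detect_shifts(y, tree55)
        m2 = detect_shifts(y, tree55)
        assert m1.shift_edges == m2.shift_edges
        assert m1.criterion == m2.criterion

    def test_strong_shift_recovered_within_one_edge(self, tree55):
        """A 5-stationary-SD optimum shift on a small clade is recovered at
        the true edge or an adjacent one."""
        edge = next(
            v for v in range(1, tree55.n_nodes) if 5 <= len(tree55.tips_below(v)) <= 8
        )
        alpha, s2 = 0.1, 0.02
        dtheta = 5 * np.sqrt(s2 / (2 * alpha))
        ok = 0
        reps = 10
        for i in range(reps):
            y = simulate_ou_shifts(tree55, (edge,), alpha, s2, [0.0, dtheta], seed=300 + i)
            found = detect_shifts(y, tree55)
            near = {edge, int(tree55.parent[edge])} | set(tree55.children[edge])
            ok += bool(set(found.shift_edges) & near)
        assert ok >= 9

    def test_empty_shift_set_is_valid(self, tree55):
        y = 1e-3 * np.arange(55.0)
        m = detect_shifts(y, tree55)
        assert isinstance(m.shift_edges, tuple)

    def test_max_shifts_guard(self, tree55):
        with pytest.raises(ValueError, match="guard"):
            detect_shifts(np.zeros(55), tree55, max_shifts=30)

    def test_alternatives_are_sorted(self, tree55):
        y = simulate_bm(tree55, 0.01, 0.0, seed=88)
        m = detect_shifts(y, tree55, keep_top=3)
        crits = [c for _, c in m.alternatives]
        assert crits == sorted(crits)


class TestShiftSupport:
    def test_near_noiseless_support_is_full(self, tree55):
        edge = next(
            v for v in range(1, tree55.n_nodes) if 5 <= len(tree55.tips_below(v)) <= 8
        )
        y = np.zeros(55)
        y[tree55.tips_below(edge)] += 10.0
        y += np.random.default_rng(0).normal(0, 0.01, 55)
        m = detect_shifts(y, tree55)
        assert edge in m.shift_edges
        with pytest.warns(UserWarning, match="unstable"):
            shift_support(m, B=20, seed=5)
        assert m.support[edge] == pytest.approx(100.0)

    def test_seed_stability(self, tree55):
        edge = next(
            v for v in range(1, tree55.n_nodes) if 5 <= len(tree55.tips_below(v)) <= 8
        )
        sd = np.sqrt(0.01 * tree55.depth)
        y = simulate_bm(tree55, 0.01, 0.0, seed=41)
        y[tree55.tips_below(edge)] += 5 * sd
        m = detect_shifts(y, tree55)
        if edge not in m.shift_edges:
            pytest.fail("setup: strong shift not detected")
        s1 = dict(shift_support(m, B=60, seed=1).support)
        s2 = dict(shift_support(m, B=60, seed=2).support)
        assert abs(s1[edge] - s2[edge]) < 15


class TestSnr:
    def test_zero_when_no_shift(self, tree55):
        y = simulate_bm(tree55, 0.01, 0.0, seed=4)
        m = ou_regime_fit(y, tree55, ())
        assert snr(m) == 0.0

    def test_homogeneous_in_theta_differences(self, tree55):
        edge = next(
            v for v in range(1, tree55.n_nodes) if 5 <= len(tree55.tips_below(v)) <= 8
        )
        y = simulate_ou_shifts(tree55, (edge,), 0.1, 0.02, [0.0, 2.0], seed=9)
        m = ou_regime_fit(y, tree55, (edge,))
        m2 = ou_regime_fit(y, tree55, (edge,))
        m2.theta = 2 * m.theta  # double all optimum differences
        assert snr(m2) == pytest.approx(2 * snr(m))

    def test_scaling_with_sigma2(self, tree55):
        edge = next(
            v for v in range(1, tree55.n_nodes) if 5 <= len(tree55.tips_below(v)) <= 8
        )
        y = simulate_ou_shifts(tree55, (edge,), 0.1, 0.02, [0.0, 2.0], seed=10)
        m = ou_regime_fit(y, tree55, (edge,))
        m2 = ou_regime_fit(y, tree55, (edge,))
        m2.sigma2 = 4 * m.sigma2
        assert snr(m2) == pytest.approx(snr(m) / 2)


class TestGradeMagnitude:
    @pytest.fixture
    def paired_tables(self, rng):
        names_a = [f"P{i}" for i in range(10)]
        names_b = [f"C{i}" for i in range(10)]
        base = pd.DataFrame(
            rng.uniform(5, 50, size=(10, 10)),
            index=names_b,
            columns=[f"m{j}" for j in range(10)],
        )
        meas = pd.concat([base.set_axis(names_a, axis=0), base])
        bl = pd.Series(
            np.concatenate([np.linspace(100, 1000, 10)] * 2),
            index=names_a + names_b,
        )
        clades = pd.Series(
            ["primate"] * 10 + ["carnivoran"] * 10, index=names_a + names_b
        )
        return meas, bl, clades

    def test_identical_clades_ratio_one(self, paired_tables):
        meas, bl, clades = paired_tables
        out = grade_magnitude(meas, bl, clades)
        assert out["mean_ratio"] == pytest.approx(1.0)
        assert out["sd_ratio"] == pytest.approx(0.0)

    def test_scaled_primates_ratio(self, paired_tables):
        meas, bl, clades = paired_tables
        meas.loc[[s for s in meas.index if s.startswith("P")]] *= 1.5
        out = grade_magnitude(meas, bl, clades)
        assert out["mean_ratio"] == pytest.approx(1.5)

    def test_fewer_pairs_warns(self, paired_tables):
        meas, bl, clades = paired_tables
        keep = [s for s in meas.index if s != "P9"]
        with pytest.warns(UserWarning, match="pairs"):
            out = grade_magnitude(meas.loc[keep], bl[keep], clades[keep], n_pairs=10)
        assert len(out["pairs"]) == 9

    def test_missing_clade_raises(self, paired_tables):
        meas, bl, clades = paired_tables
        keep = [s for s in meas.index if s.startswith("P")]
        with pytest.raises(ValueError, match="both clades"):
            grade_magnitude(meas.loc[keep], bl[keep], clades[keep])
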