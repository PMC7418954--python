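import numpy as np
import pytest
from scipy import stats

from phylarynx import (
    ancestral_states,
    clade_rate,
    pic,
    rate_posterior,
    rate_ratio_test,
    read_tree,
    simulate_bm,
    simulate_tree,
    trait_vs_body_rate,
    vcv_bm,
)


def gls_ancestral_oracle(tree, y):
    """Independent oracle: conditional means from the full BM covariance.

    With a flat root prior, anc(a) = root + c_a' V^{-1} (y - root), where
    root = (1'V^{-1}1)^{-1} 1'V^{-1} y and c_a[i] is the shared path length
    between internal node a and tip i.
    """
    V = vcv_bm(tree)
    Vi = np.linalg.inv(V)
    one = np.ones(tree.n_tips)
    root = (one @ Vi @ y) / (one @ Vi @ one)
    out = np.zeros(tree.n_nodes)
    paths = [set(tree.path_to_root(int(t))) - {0} for t in tree.tip_ids]
    for a in range(tree.n_nodes):
        if tree.is_tip[a]:
            pos = list(tree.tip_ids).index(a)
            out[a] = y[pos]
            continue
        pa = set(tree.path_to_root(a)) - {0}
        c = np.array(
            [sum(tree.blen[v] for v in (pa & paths[i])) for i in range(tree.n_tips)]
        )
        out[a] = root + c @ Vi @ (y - root)
    return out


class TestPic:
    def test_two_tip_contrast(self):
        t = read_tree("(A:1.0,B:1.0);")
        y = np.zeros(2)
        y[t.tip_labels.index("A")] = 0.0
        y[t.tip_labels.index("B")] = 2.0
        c = pic(t, y)
        assert len(c) == 1
        assert abs(c[0]) == pytest.approx(np.sqrt(2.0))

    def test_constant_trait_zero_contrasts(self, tree55):
        assert np.allclose(pic(tree55, np.full(55, 3.3)), 0.0)

    def test_contrast_count(self, tree55):
        assert len(pic(tree55, np.arange(55.0))) == 54

    def test_mean_square_estimates_rate(self):
        t = simulate_tree(20, seed=1, depth=10.0)
        rates = [np.mean(pic(t, simulate_bm(t, 1.0, 0.0, seed=s)) ** 2) for s in range(400)]
        # unbiased: mean over replicates within 2 SE of 1
        se = np.std(rates) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - 1.0) < 2 * se + 0.02


class TestCladeRate:
    @pytest.fixture
    def clade(self, tree55):
        return [l for l in tree55.tip_labels if l.startswith("P")]

    def test_quadratic_in_trait_scale(self, tree55, clade):
        y = simulate_bm(tree55, 0.01, 0.0, seed=2)
        assert clade_rate(2 * y, tree55, clade) == pytest.approx(
            4 * clade_rate(y, tree55, clade)
        )

    def test_halves_when_time_doubles(self, tree55, clade):
        y = simulate_bm(tree55, 0.01, 0.0, seed=3)
        from phylarynx.simulate import _rescale_newick

        t2 = read_tree(_rescale_newick(tree55, 2.0))
        y2 = np.array([y[tree55.tip_index(l)] for l in t2.tip_labels])
        assert clade_rate(y2, t2, clade) == pytest.approx(
            clade_rate(y, tree55, clade) / 2
        )

    def test_non_monophyletic_raises(self, tree55):
        mixed = tree55.tip_labels[:3] + tree55.tip_labels[-3:]
        with pytest.raises(ValueError, match="monophyletic"):
            clade_rate(np.arange(55.0), tree55, mixed)

    def test_small_bias(self):
        t = simulate_tree(30, seed=4, depth=20.0)
        est = [
            np.mean(pic(t, simulate_bm(t, 1.0, 0.0, seed=100 + s)) ** 2)
            for s in range(300)
        ]
        assert np.mean(est) == pytest.approx(1.0, rel=0.05)


class TestRateRatioTest:
    def test_scale_invariance(self, tree55):
        pr = [l for l in tree55.tip_labels if l.startswith("P")]
        ca = [l for l in tree55.tip_labels if l.startswith("C")]
        y = simulate_bm(tree55, 0.01, 0.0, seed=5)
        r1 = rate_ratio_test(y, tree55, pr, ca, n_perm=999, seed=0)
        r2 = rate_ratio_test(7.3 * y, tree55, pr, ca, n_perm=999, seed=0)
        assert r1.ratio == pytest.approx(r2.ratio)
        assert r1.P == r2.P

    def test_p_corrected_and_in_range(self, tree55):
        pr = [l for l in tree55.tip_labels if l.startswith("P")]
        ca = [l for l in tree55.tip_labels if l.startswith("C")]
        y = simulate_bm(tree55, 0.01, 0.0, seed=6)
        r = rate_ratio_test(y, tree55, pr, ca, n_perm=999, seed=1)
        assert 1 / 1000 <= r.P <= 1.0

    def test_low_n_perm_warns(self, tree55):
        pr = [l for l in tree55.tip_labels if l.startswith("P")]
        ca = [l for l in tree55.tip_labels if l.startswith("C")]
        y = simulate_bm(tree55, 0.01, 0.0, seed=7)
        with pytest.warns(UserWarning, match="coarse"):
            rate_ratio_test(y, tree55, pr, ca, n_perm=99, seed=1)


class TestRatePosterior:
    def test_posterior_mean_matches_analytic(self, tree55):
        pr = [l for l in tree55.tip_labels if l.startswith("P")]
        y = simulate_bm(tree55, 0.01, 0.0, seed=8)
        s2 = clade_rate(y, tree55, pr)
        m = len(pr) - 1
        draws = rate_posterior(y, tree55, pr, n_draws=200_000, seed=3)
        assert draws.mean() == pytest.approx(m * s2 / (m - 2), rel=0.02)

    def test_matches_analytic_inverse_gamma(self, tree55):
        pr = [l for l in tree55.tip_labels if l.startswith("P")]
        y = simulate_bm(tree55, 0.01, 0.0, seed=9)
        s2 = clade_rate(y, tree55, pr)
        m = len(pr) - 1
        draws = rate_posterior(y, tree55, pr, n_draws=10_000, seed=4)
        dist = stats.invgamma(a=m / 2, scale=m * s2 / 2)
        ks = stats.kstest(draws, dist.cdf).statistic
        assert ks < 0.02

    def test_seed_stability(self, tree55):
        pr = [l for l in tree55.tip_labels if l.startswith("P")]
        y = simulate_bm(tree55, 0.01, 0.0, seed=10)
        m1 = rate_posterior(y, tree55, pr, n_draws=10_000, seed=1).mean()
        m2 = rate_posterior(y, tree55, pr, n_draws=10_000, seed=2).mean()
        assert abs(m1 - m2) / m1 < 0.01


class TestTraitVsBodyRate:
    def test_identical_traits(self, tree55):
        y = simulate_bm(tree55, 0.01, 0.0, seed=11)
        ratio, P = trait_vs_body_rate(y, y, tree55, n_perm=999, seed=0)
        assert ratio == pytest.approx(1.0)
        assert P > 0.5

    def test_power_for_faster_trait(self):
        t = simulate_tree(26, seed=12, depth=65.0)
        hits = 0
        reps = 25
        for i in range(reps):
            b = simulate_bm(t, 1.0, 0.0, seed=700 + i)
            a = simulate_bm(t, 3.0, 0.0, seed=800 + i)
            _, P = trait_vs_body_rate(a, b, t, n_perm=499, seed=i)
            hits += P < 0.05
        assert hits >= 0.6 * reps

    def test_scale_mismatch_warns(self, tree55):
        y = simulate_bm(tree55, 0.01, 0.0, seed=13)
        with pytest.warns(UserWarning, match="scale"):
            trait_vs_body_rate(y * 1e4, y, tree55, n_perm=99, seed=0)


class TestAncestralStates:
    def test_two_tip_symmetry(self):
        t = read_tree("(A:1.0,B:1.0);")
        y = np.zeros(2)
        y[t.tip_labels.index("A")] = 0.0
        y[t.tip_labels.index("B")] = 2.0
        anc = ancestral_states(y, t)
        assert anc.root_value == pytest.approx(1.0)

    def test_fast_branch_downweights_tip(self):
        t = read_tree("(A:1.0,B:1.0);")
        y = np.zeros(2)
        ia = int(t.tip_ids[t.tip_labels.index("A")])
        y[t.tip_labels.index("A")] = 0.0
        y[t.tip_labels.index("B")] = 2.0
        anc = ancestral_states(y, t, regime_rates={ia: 1e9})
        # tip A's branch has enormous variance; root follows tip B
        assert anc.root_value == pytest.approx(2.0, abs=1e-6)

    def test_equal_rates_match_gls_oracle(self):
        t = simulate_tree(15, seed=14, depth=30.0)
        y = simulate_bm(t, 0.5, 1.0, seed=15)
        anc = ancestral_states(y, t)
        oracle = gls_ancestral_oracle(t, y)
        assert np.allclose(anc.values, oracle, atol=1e-8)

    def test_tip_values_preserved(self, tree55):
        y = simulate_bm(tree55, 0.01, 0.0, seed=16)
        anc = ancestral_states(y, tree55)
        assert np.allclose(anc.values[tree55.tip_ids], y)

    def test_nonpositive_rate_raises(self, tree55):
        with pytest.raises(ValueError, match="positive"):
            ancestral_states(np.zeros(55), tree55, regime_rates={1: 0.0})

    def test_segments_for_phenogram(self, tree55):
        y = simulate_bm(tree55, 0.01, 0.0, seed=17)
        anc = ancestral_states(y, tree55)
        assert len(anc.segments) == tree55.n_nodes - 1
        for ph, pv, ch, cv in anc.segments:
            assert ch > ph  # children are younger than parents
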