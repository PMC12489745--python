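"""Nei, Weir-Cockerham and allele-matching estimators; distances; NJ."""

import numpy as np
import pytest

from popgea.diversity import (
    DistanceMatrix,
    beta_fst,
    nei_D,
    nei_basic_stats,
    nj_tree,
    pairwise_fst,
    wc_components,
    wc_stats,
)
from popgea.simulate import SimConfig, simulate

from conftest import make_gm


def hwe_two_pop_gm(seed=0, n=200, L=400, delta=0.0):
    """Two HWE populations with frequency offset delta."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, L)
    g1 = rng.binomial(2, p, (n, L)).astype(np.int8)
    g2 = rng.binomial(2, np.clip(p + delta, 0.01, 0.99), (n, L)).astype(np.int8)
    return make_gm(np.vstack([g1, g2]), pops=["p1"] * n + ["p2"] * n)


class TestNei:
    def test_equal_frequency_hwe_fst_near_zero(self):
        gm = hwe_two_pop_gm(seed=1)
        st = nei_basic_stats(gm, gm.individuals["region"])
        assert abs(st.Fst) < 0.02
        assert abs(st.Fis) < 0.02

    def test_fixed_difference_limit(self):
        # pop1 fixed alt, pop2 fixed ref at every locus
        n = 50
        gm = make_gm(
            np.vstack([np.full((n, 20), 2, np.int8), np.zeros((n, 20), np.int8)]),
            pops=["p1"] * n + ["p2"] * n,
        )
        st = nei_basic_stats(gm, gm.individuals["region"])
        assert st.Hs == pytest.approx(0.0, abs=1e-12)
        assert st.Fst == pytest.approx(1.0, abs=0.02)
        assert st.Ht == pytest.approx(0.5, abs=0.02)

    def test_hand_computed_two_pop_two_locus_oracle(self):
        # pop A: genotypes (0,1,2); pop B: (1,2,2) at locus 1
        #        (0,0,1)            (1,1,2) at locus 2
        gm = make_gm(
            np.array([[0, 0], [1, 0], [2, 1], [1, 1], [2, 1], [2, 2]], np.int8),
            pops=["A", "A", "A", "B", "B", "B"],
        )
        st = nei_basic_stats(gm, gm.individuals["region"])

        # independent step-by-step computation of the corrected estimators
        def locus(pA, pB, hoA, hoB, n=3):
            nh = 2 / (1 / n + 1 / n)
            ho = (hoA + hoB) / 2
            hs_raw = (2 * pA * (1 - pA) + 2 * pB * (1 - pB)) / 2
            hs = nh / (nh - 1) * (hs_raw - ho / (2 * nh))
            pbar = (pA + pB) / 2
            ht = 2 * pbar * (1 - pbar) + hs / (2 * nh) - ho / (4 * nh)
            return ho, hs, ht

        l1 = locus(pA=3 / 6, pB=5 / 6, hoA=1 / 3, hoB=1 / 3)
        l2 = locus(pA=1 / 6, pB=4 / 6, hoA=1 / 3, hoB=2 / 3)
        Ho = (l1[0] + l2[0]) / 2
        Hs = (l1[1] + l2[1]) / 2
        Ht = (l1[2] + l2[2]) / 2
        assert st.Ho == pytest.approx(Ho, abs=1e-12)
        assert st.Hs == pytest.approx(Hs, abs=1e-12)
        assert st.Ht == pytest.approx(Ht, abs=1e-12)
        assert st.Fst == pytest.approx(1 - Hs / Ht, abs=1e-12)


class TestWeirCockerham:
    def test_null_theta_near_zero(self):
        gm = hwe_two_pop_gm(seed=2)
        theta, f, _ = wc_stats(gm, gm.individuals["region"])
        assert abs(theta) < 0.02

    def test_single_locus_hand_components(self):
        # two pops of 2 individuals; genotypes pop1: 0,1 ; pop2: 2,1
        gm = make_gm(np.array([[0], [1], [2], [1]], np.int8),
                     pops=["x", "x", "y", "y"])
        comp = wc_components(gm, gm.individuals["region"])

        # hand derivation per the 1984 component formulas
        r, n1, n2 = 2, 2, 2
        p1, p2 = 1 / 4, 3 / 4
        h1, h2 = 1 / 2, 1 / 2
        nbar = 2.0
        nc = (4 - (4 + 4) / 4) / 1  # = 2
        pbar = (n1 * p1 + n2 * p2) / 4
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / 4
        a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - s2 / 2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        assert comp.loc[0, "a"] == pytest.approx(a, abs=1e-12)
        assert comp.loc[0, "b"] == pytest.approx(b, abs=1e-12)
        assert comp.loc[0, "c"] == pytest.approx(c, abs=1e-12)

    def test_theta_recovers_drift_parameter(self):
        gm, _, _ = simulate(
            SimConfig(seed=50, n_pops=5, n_per_pop=40, n_loci=3000, fst_per_pop=0.15)
        )
        theta, _, _ = wc_stats(gm, gm.individuals["region"])
        assert theta == pytest.approx(0.15, abs=0.02)

    def test_monomorphic_only_errors(self):
        gm = make_gm(np.zeros((6, 3), np.int8), pops=["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError):
            wc_stats(gm, gm.individuals["region"])

    def test_agrees_with_nei_at_many_balanced_pops(self):
        # the two estimators converge as the number of populations grows
        gm, _, _ = simulate(
            SimConfig(seed=51, n_pops=10, n_per_pop=30, n_loci=2000, fst_per_pop=0.1)
        )
        theta, _, _ = wc_stats(gm, gm.individuals["region"])
        st = nei_basic_stats(gm, gm.individuals["region"])
        assert abs(theta - st.Fst) < 0.02


class TestBetaFst:
    def test_panmictic_null(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, 3000)
        g = rng.binomial(2, p, (80, 3000)).astype(np.int8)
        gm = make_gm(g, pops=np.repeat(list("abcd"), 20))
        bs = beta_fst(gm, gm.individuals["region"], n_boot=50, seed=0)
        assert np.all(np.abs(bs.beta) < 0.02)

    def test_drifted_population_is_maximum(self):
        gm, _, _ = simulate(
            SimConfig(seed=52, n_pops=5, n_per_pop=30, n_loci=2000,
                      fst_per_pop=(0.1, 0.1, 0.1, 0.1, 0.5))
        )
        bs = beta_fst(gm, gm.individuals["region"], n_boot=100, seed=1)
        assert bs.labels[np.argmax(bs.beta)] == "pop5"

    def test_bootstrap_deterministic_and_covering(self):
        gm, _, _ = simulate(
            SimConfig(seed=53, n_pops=3, n_per_pop=20, n_loci=500, fst_per_pop=0.1)
        )
        a = beta_fst(gm, gm.individuals["region"], n_boot=100, seed=7)
        b = beta_fst(gm, gm.individuals["region"], n_boot=100, seed=7)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)
        assert np.all(a.ci_low <= a.beta + 1e-9)
        assert np.all(a.beta <= a.ci_high + 1e-9)

    def test_n_boot_bound(self):
        gm = hwe_two_pop_gm(seed=5, n=10, L=50)
        with pytest.raises(ValueError):
            beta_fst(gm, gm.individuals["region"], n_boot=1)


class TestPairwiseFst:
    def test_random_split_near_zero(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.2, 0.8, 1000)
        g = rng.binomial(2, p, (60, 1000)).astype(np.int8)
        gm = make_gm(g, pops=rng.permutation(["a"] * 30 + ["b"] * 30))
        fst, lo, hi = pairwise_fst(gm, gm.individuals["region"], n_boot=50, seed=0)
        assert abs(fst.values[0, 1]) < 0.02

    def test_rank_concordance_and_structure(self):
        gm, _, _ = simulate(
            SimConfig(seed=54, n_pops=3, n_per_pop=30, n_loci=1500,
                      fst_per_pop=(0.05, 0.15, 0.15))
        )
        fst, lo, hi = pairwise_fst(gm, gm.individuals["region"], n_boot=50, seed=0)
        v = fst.values
        assert np.allclose(v, v.T) and np.all(np.diag(v) == 0)
        # pair (pop2, pop3) carries the most combined drift
        pairs = {(0, 1): v[0, 1], (0, 2): v[0, 2], (1, 2): v[1, 2]}
        assert max(pairs, key=pairs.get) == (1, 2)
        assert np.all(lo.values[np.triu_indices(3, 1)] <= v[np.triu_indices(3, 1)])


class TestNeiD:
    def test_identical_profiles_zero(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, (10, 100)).astype(np.int8)
        gm = make_gm(np.vstack([g, g]), pops=["a"] * 10 + ["b"] * 10)
        D = nei_D(gm, gm.individuals["region"])
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_hand_case(self):
        # p_x = 1, p_y = 0.5 at a single locus: D = ln sqrt(2)
        gm = make_gm(np.array([[2], [2], [1], [1]], np.int8),
                     pops=["x", "x", "y", "y"])
        D = nei_D(gm, gm.individuals["region"])
        assert D.values[0, 1] == pytest.approx(np.log(np.sqrt(2)), abs=1e-12)

    def test_nonnegative_on_simulations(self):
        gm, _, _ = simulate(
            SimConfig(seed=55, n_pops=4, n_per_pop=15, n_loci=500, fst_per_pop=0.2)
        )
        D = nei_D(gm, gm.individuals["region"])
        assert np.all(D.values >= 0)

    def test_unbiased_variant_close_at_large_n(self):
        gm = hwe_two_pop_gm(seed=8, n=150, L=300, delta=0.2)
        d72 = nei_D(gm, gm.individuals["region"]).values[0, 1]
        d78 = nei_D(gm, gm.individuals["region"], variant="1978").values[0, 1]
        assert d78 == pytest.approx(d72, abs=0.01)


class TestNJ:
    def test_recovers_additive_four_leaf_metric(self):
        # ((A:1,B:2):5,(C:3,D:4)) -> unique additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
            float,
        )
        nwk = nj_tree(DistanceMatrix(labels, d))
        import io
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        # leaf-to-leaf path lengths reproduce the input metric exactly
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        d[i, j], abs=1e-9
                    )

    def test_matches_skbio_nj_on_additive_metric(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(9)
        # random additive tree metric via random leaf depths on a caterpillar
        base = np.array(
            [
                [0, 2, 6, 8, 9],
                [2, 0, 6, 8, 9],
                [6, 6, 0, 4, 5],
                [8, 8, 4, 0, 3],
                [9, 9, 5, 3, 0],
            ],
            float,
        )
        ours = nj_tree(DistanceMatrix(labels, base))
        theirs = skbio_nj(SkbioDM(base, labels))
        import io
        from skbio import TreeNode

        t1 = TreeNode.read(io.StringIO(ours))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d1 = t1.find(a).distance(t1.find(b))
                    d2 = theirs.find(a).distance(theirs.find(b))
                    assert d1 == pytest.approx(d2, abs=1e-9)

    def test_three_leaves_closed_form(self):
        labels = ["a", "b", "c"]
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        nwk = nj_tree(DistanceMatrix(labels, d))
        import io
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        assert tree.find("a").length == pytest.approx((5 + 9 - 10) / 2)
        assert tree.find("b").length == pytest.approx((5 + 10 - 9) / 2)
        assert tree.find("c").length == pytest.approx((9 + 10 - 5) / 2)

    def test_leaf_set_preserved(self):
        gm, _, _ = simulate(
            SimConfig(seed=56, n_pops=5, n_per_pop=10, n_loci=300, fst_per_pop=0.2)
        )
        D = nei_D(gm, gm.individuals["region"])
        nwk = nj_tree(D)
        import io
        from skbio import TreeNode

        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == set(D.labels)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
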