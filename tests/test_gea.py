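"""Environmental predictor pruning, pRDA, LFMM and candidate intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from popgea.gea import (
    individual_allele_freq,
    intersect_candidates,
    lfmm_scan,
    prda,
    prep_env,
    rda_candidates,
    CandidateSet,
    PRDAResult,
)
from popgea.qvalue import qvalues
from popgea.simulate import SimConfig, simulate

from conftest import make_gm


class TestPrepEnv:
    def test_perfectly_correlated_pair_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        env = pd.DataFrame({"id": [f"i{k}" for k in range(50)],
                            "a": x, "b": 2 * x + 1, "c": rng.normal(size=50)})
        kept, cond, log = prep_env(env)
        assert list(kept.columns) == ["a", "c"]
        assert any("b" in line for line in log)

    def test_orthogonal_design_untouched(self):
        n = 64
        env = pd.DataFrame({
            "id": [f"i{k}" for k in range(n)],
            "a": np.tile([1.0, -1.0], n // 2),
            "b": np.repeat([1.0, -1.0], n // 2),
            "c": np.tile([1.0, 1.0, -1.0, -1.0], n // 4),
        })
        kept, cond, _ = prep_env(env)
        assert list(kept.columns) == ["a", "b", "c"]
        assert cond.shape[1] == 0

    def test_vif_stage_matches_step_by_step_oracle(self):
        # 12 variables with a planted collinear block; re-run the removal
        # loop independently with statsmodels' VIF at every step
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(1)
        n = 80
        base = rng.normal(size=(n, 8))
        block = base[:, :3] @ rng.normal(size=(3, 4)) + 0.3 * rng.normal(size=(n, 4))
        X = np.column_stack([base, block])
        cols = [f"v{k:02d}" for k in range(12)]
        env = pd.DataFrame(X, columns=cols)
        env.insert(0, "id", [f"i{k}" for k in range(n)])

        kept, cond, _ = prep_env(env, r_max=0.95, vif_max=3.0)

        def oracle(frame, vif_max):
            cols = list(frame.columns)
            removed = []
            while len(cols) > 1:
                Z = (frame[cols] - frame[cols].mean()) / frame[cols].std()
                Z = Z.to_numpy()
                vifs = [variance_inflation_factor(
                    np.column_stack([np.ones(len(Z)), Z]), j + 1)
                    for j in range(len(cols))]
                worst = int(np.argmax(vifs))
                if vifs[worst] <= vif_max:
                    break
                removed.append(cols.pop(worst))
            return cols, removed

        # replicate the correlation stage first
        frame = env.set_index("id")
        corr = frame.corr().abs()
        drop = set()
        cs = list(frame.columns)
        for i in range(len(cs)):
            if cs[i] in drop:
                continue
            for j in range(i + 1, len(cs)):
                if cs[j] not in drop and corr.iloc[i, j] > 0.95:
                    drop.add(cs[j])
        stage1 = [c for c in cs if c not in drop]
        exp_kept, exp_removed = oracle(frame[stage1], 3.0)
        assert list(kept.columns) == exp_kept
        assert list(cond.columns) == exp_removed

    def test_missing_data_rejected(self):
        env = pd.DataFrame({"id": ["a", "b"], "x": [1.0, np.nan], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            prep_env(env)


class TestIndividualAlleleFreq:
    def test_dosage_halving_and_imputation(self):
        gm = make_gm(np.array([[1, 2, -1], [2, 0, 1], [1, 2, 1]], np.int8))
        Y = individual_allele_freq(gm)
        assert Y[0, 0] == 0.5 and Y[1, 0] == 1.0
        # missing entry at (0,2): site mean dosage is 1 -> 0.5
        assert Y[0, 2] == pytest.approx(0.5)


def planted_dataset(seed=42, n=120, L=1500, signal_snps=40, r_target=0.35):
    """Genotype frequencies with a planted linear dependence on env x1."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    p = rng.uniform(0.2, 0.8, L)
    G = rng.binomial(2, p, (n, L)).astype(float)
    beta = r_target * np.sqrt(G[:, :signal_snps].var(axis=0))
    G[:, :signal_snps] += np.outer(x1, beta / x1.std())
    Y = G / 2.0
    X = pd.DataFrame({"x1": x1, "x2": x2})
    return Y - Y.mean(axis=0) + 0.5, X, np.arange(signal_snps)


class TestPRDA:
    def test_single_variable_reduces_to_regression(self):
        Y, X, _ = planted_dataset(seed=1, n=60, L=200, signal_snps=10)
        res = prda(Y, X[["x1"]], Z=None, n_perm=29, seed=0)
        # canonical variance fraction equals the mean squared multiple
        # correlation from direct per-SNP regression
        x = (X["x1"] - X["x1"].mean()) / X["x1"].std()
        Yc = Y - Y.mean(axis=0)
        fitted = np.outer(x, (x @ Yc) / (x @ x))
        r2_direct = (fitted**2).sum() / (Yc**2).sum()
        r2_rda = res.eigenvalues.sum() / (res.total_variance / (len(Y) - 1))
        assert r2_rda == pytest.approx(r2_direct, abs=1e-10)

    def test_empty_conditioning_equals_plain_rda(self):
        Y, X, _ = planted_dataset(seed=2, n=50, L=150, signal_snps=5)
        a = prda(Y, X, Z=None, n_perm=9, seed=3)
        b = prda(Y, X, Z=np.empty((len(Y), 0)), n_perm=9, seed=3)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-8)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-8)
        assert a.r2_adj_full == pytest.approx(b.r2_adj_full, abs=1e-8)

    def test_adjusted_r2_closed_form(self):
        Y, X, _ = planted_dataset(seed=3, n=80, L=100, signal_snps=0)
        res = prda(Y, X, Z=None, n_perm=9, seed=0)
        Yc = Y - Y.mean(axis=0)
        Xs = (X - X.mean()) / X.std()
        A = np.column_stack([np.ones(len(Y)), Xs])
        coef, *_ = np.linalg.lstsq(A, Yc, rcond=None)
        fitted = A @ coef
        r2 = (fitted**2).sum() / (Yc**2).sum()
        n, p = len(Y), X.shape[1]
        assert res.r2_adj_full == pytest.approx(
            1 - (1 - r2) * (n - 1) / (n - p - 1), abs=1e-10
        )

    def test_planted_signal_axis_significant(self):
        Y, X, sig = planted_dataset(seed=4)
        res = prda(Y, X, Z=None, n_perm=99, seed=1)
        assert res.axis_pvalues[0] <= 0.05
        # loadings of axis 1 enriched for the dependent SNPs
        lo = np.abs(res.loadings[:, 0])
        assert lo[sig].mean() > 3 * np.delete(lo, sig).mean()

    def test_eigenvalue_sum_bounded_by_total_variance(self):
        Y, X, _ = planted_dataset(seed=5, n=40, L=80, signal_snps=5)
        res = prda(Y, X, Z=None, n_perm=9, seed=0)
        assert res.eigenvalues.sum() <= res.total_variance / (len(Y) - 1) + 1e-9

    def test_variance_partition_fractions_bounded(self):
        Y, X, _ = planted_dataset(seed=6)
        Z = np.random.default_rng(0).normal(size=(len(Y), 3))
        res = prda(Y, X, Z=Z, n_perm=9, seed=0)
        assert res.r2_adj_climate <= res.r2_adj_full + 1e-9
        assert res.r2_adj_structure <= res.r2_adj_full + 1e-9

    def test_too_few_individuals_errors(self):
        Y = np.random.default_rng(0).random((5, 10))
        X = pd.DataFrame({"a": np.arange(5.0), "b": np.arange(5.0) ** 2,
                          "c": np.arange(5.0) % 2, "d": np.arange(5.0) % 3})
        with pytest.raises(ValueError):
            prda(Y, X, Z=None)


class TestRDACandidates:
    def _null_result(self, L=4000, axes=3, seed=0):
        rng = np.random.default_rng(seed)
        loadings = rng.normal(size=(L, axes))
        return PRDAResult(
            eigenvalues=np.ones(axes), axis_scores=np.zeros((10, axes)),
            loadings=loadings, r2_adj_full=0.1, r2_adj_climate=0.05,
            r2_adj_structure=0.05, axis_pvalues=np.ones(axes),
            retained_axes=axes, total_variance=1.0,
        )

    def test_gaussian_null_tail_fraction(self):
        res = self._null_result()
        L = 4000
        ids = np.array([f"s{j}" for j in range(L)])
        rng = np.random.default_rng(1)
        Y = rng.random((10, L))
        env = pd.DataFrame({"e1": rng.normal(size=10)})
        for sd_mult in (2.5, 3.0):
            cs = rda_candidates(res, ids, Y, env, retained_axes=1, sd_mult=sd_mult)
            expected = 2 * norm.sf(sd_mult)
            assert len(cs) / L == pytest.approx(expected, abs=2 * expected)

    def test_threshold_nesting(self):
        res = self._null_result(seed=2)
        L = 4000
        ids = np.array([f"s{j}" for j in range(L)])
        rng = np.random.default_rng(3)
        Y = rng.random((10, L))
        env = pd.DataFrame({"e1": rng.normal(size=10)})
        strict = rda_candidates(res, ids, Y, env, 3, 3.0).site_ids
        loose = rda_candidates(res, ids, Y, env, 3, 2.5).site_ids
        assert strict <= loose

    def test_planted_snps_assigned_to_driving_variable(self):
        Y, X, sig = planted_dataset(seed=7)
        res = prda(Y, X, Z=None, n_perm=9, seed=0)
        ids = np.array([f"s{j}" for j in range(Y.shape[1])])
        cs = rda_candidates(res, ids, Y, X, retained_axes=2, sd_mult=2.5)
        hits = cs.table[cs.table["site"].isin(ids[sig])]
        assert len(hits) > 0
        assert (hits["env_var"] == "x1").mean() >= 0.8


class TestLFMM:
    def test_K0_small_lambda_equals_ols(self):
        Y, X, _ = planted_dataset(seed=8, n=50, L=120, signal_snps=10)
        res = lfmm_scan(Y, X[["x1"]], K=0, lam=1e-12, fdr=0.1)
        x = X["x1"].to_numpy()
        x = (x - x.mean()) / x.std()
        Yc = Y - Y.mean(axis=0)
        ols = (x @ Yc) / (x @ x)
        np.testing.assert_allclose(res.effects[:, 0], ols, atol=1e-8)

    def test_confounded_null_uniform_pvalues(self):
        # population mean differences but no environmental effect: with
        # K latent factors the p-values stay calibrated
        gm, env, _ = simulate(
            SimConfig(seed=60, n_pops=3, n_per_pop=40, n_loci=2000,
                      fst_per_pop=0.15, n_env_vars=1, env_correlation=0.9)
        )
        Y = individual_allele_freq(gm)
        res = lfmm_scan(Y, env.set_index("id"), K=3, fdr=0.1,
                        site_ids=gm.site_ids)
        p = res.pvalues_adj[np.isfinite(res.pvalues_adj[:, 0]), 0]
        assert kstest(p, "uniform").pvalue > 0.01

    def test_planted_effect_recall_and_fdr(self):
        recalls, fdrs = [], []
        for seed in range(5):
            gm, env, truth = simulate(
                SimConfig(seed=70 + seed, n_pops=2, n_per_pop=50, n_loci=2000,
                          fst_per_pop=0.02, n_env_vars=2, env_correlation=0.6,
                          n_adaptive=50, effect_size=1.5)
            )
            Y = individual_allele_freq(gm)
            res = lfmm_scan(Y, env.set_index("id"), K=2, fdr=0.1,
                            site_ids=gm.site_ids)
            sig = set(res.significant(0.1)["site"])
            truth_ids = truth.adaptive_site_ids()
            recalls.append(len(sig & truth_ids) / len(truth_ids))
            fdrs.append(len(sig - truth_ids) / max(len(sig), 1))
        assert np.mean(recalls) >= 0.6
        assert np.mean(fdrs) <= 0.2

    def test_K_bound(self):
        Y = np.random.default_rng(0).random((10, 20))
        with pytest.raises(ValueError):
            lfmm_scan(Y, pd.DataFrame({"a": np.arange(10.0)}), K=10)


class TestIntersection:
    def _mini(self, rda_sites, lfmm_sites, scan_sites, universe):
        rda = CandidateSet(
            table=pd.DataFrame({"site": rda_sites,
                                "env_var": ["e1"] * len(rda_sites)}),
            thresholds={"sd_mult": 3.0},
        )
        L = len(universe)
        lf = lfmm_scan(
            np.random.default_rng(0).random((12, L)),
            pd.DataFrame({"e1": np.random.default_rng(1).normal(size=12)}),
            K=0, fdr=0.1, site_ids=np.array(universe),
        )
        # overwrite q-values so exactly lfmm_sites are significant
        lf.qvalues[:, 0] = 1.0
        for s in lfmm_sites:
            lf.qvalues[universe.index(s), 0] = 0.01
        return rda, lf, scan_sites

    def test_empty_input_empty_output(self):
        uni = [f"s{j}" for j in range(20)]
        rda, lf, scan = self._mini([], ["s1"], ["s1"], uni)
        assert len(intersect_candidates(rda, lf, scan)) == 0

    def test_bounded_by_min_input(self):
        uni = [f"s{j}" for j in range(20)]
        rda, lf, scan = self._mini(["s1", "s2", "s3"], ["s1", "s2"], ["s2"], uni)
        final = intersect_candidates(rda, lf, scan)
        assert final.site_ids == {"s2"}

    def test_disjoint_universe_rejected(self):
        uni = [f"s{j}" for j in range(20)]
        rda, lf, scan = self._mini(["zzz"], ["s1"], ["s1"], uni)
        with pytest.raises(ValueError, match="universe"):
            intersect_candidates(rda, lf, scan)


class TestQvalues:
    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(500) ** 2
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_uniform_null_pi0_near_one(self):
        from popgea.qvalue import estimate_pi0

        rng = np.random.default_rng(1)
        assert estimate_pi0(rng.random(5000)) > 0.8

    def test_nan_propagation(self):
        q = qvalues(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and np.isfinite(q[0])
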