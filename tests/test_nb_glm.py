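import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from srnacontrib import nb_glm
from srnacontrib.data_io import CountMatrix, SampleDesign
from srnacontrib.nb_glm import (FitConfig, bh_adjust, build_design, fit_all,
                                fit_trend, irls_fit, lrt_interaction,
                                map_dispersion, nb_loglik,
                                profile_dispersion_mle, wald_test)

from conftest import make_counts, make_design

LN2 = np.log(2.0)


def design_2x2(reps=(2, 2, 2, 2)):
    conds, genos = [], []
    for (c, g), n in zip(
            [("reference", "wildtype"), ("stress", "wildtype"),
             ("reference", "deletion"), ("stress", "deletion")], reps):
        conds += [c] * n
        genos += [g] * n
    return SampleDesign(make_design(conds, genos))


class TestBuildDesign:
    @pytest.mark.parametrize("cond,geno,row", [
        ("stress", "wildtype", (1, 1, 1, 1)),
        ("reference", "deletion", (1, 0, 0, 0)),
        ("stress", "deletion", (1, 1, 0, 0)),
        ("reference", "wildtype", (1, 0, 1, 0)),
    ])
    def test_rows_encode_reference_levels(self, cond, geno, row):
        d = design_2x2()
        X = build_design(d)
        lib = d.table.index[(d.table["condition"] == cond)
                            & (d.table["genotype"] == geno)][0]
        assert tuple(X.loc[lib]) == row

    def test_full_design_rank_four(self):
        X = build_design(design_2x2((4, 3, 3, 3)))
        assert np.linalg.matrix_rank(X.to_numpy()) == 4


class TestNbLoglik:
    def test_poisson_limit_at_zero_count(self):
        # for y=0, mu=1 the Poisson log-density is exactly -1
        assert nb_loglik([0], [1.0], 1e-10) == pytest.approx(-1.0, abs=1e-6)

    def test_maximized_at_observed_value(self):
        y = [7]
        best = nb_loglik(y, [7.0], 0.2)
        for mu in (3.0, 5.0, 9.0, 14.0):
            assert nb_loglik(y, [mu], 0.2) < best

    def test_matches_scipy_pmf_summation(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 50, size=10)
        mu = rng.uniform(1, 40, size=10)
        alpha = 0.3
        r = 1.0 / alpha
        expected = scipy.stats.nbinom.logpmf(y, r, r / (r + mu)).sum()
        assert nb_loglik(y, mu, alpha) == pytest.approx(expected, rel=1e-10)

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            nb_loglik([1], [0.0], 0.1)


class TestIrlsFit:
    @pytest.mark.parametrize("alpha", [1e-6, 0.1, 1.0])
    def test_saturated_fit_recovers_group_means(self, alpha):
        # NB score equations give fitted group means equal to arithmetic means
        d = design_2x2((3, 3, 3, 3))
        X = build_design(d).to_numpy(dtype=float)
        y = np.array([10, 12, 14, 200, 210, 190, 50, 55, 45, 99, 101, 103],
                     dtype=float)
        res = irls_fit(y, X, np.ones(12), alpha)
        assert res.converged
        for grp in range(4):
            sel = slice(3 * grp, 3 * grp + 3)
            assert res.mu[sel].mean() == pytest.approx(y[sel].mean(), rel=1e-6)

    def test_flat_pattern_gives_zero_effects(self):
        d = design_2x2((2, 2, 2, 2))
        X = build_design(d).to_numpy(dtype=float)
        y = np.full(8, 100.0)
        res = irls_fit(y, X, np.ones(8), 0.05)
        np.testing.assert_allclose(res.beta[1:], 0.0, atol=1e-8)
        assert res.beta[0] == pytest.approx(np.log(100.0), abs=1e-8)

    def test_matches_poisson_glm_oracle_at_tiny_alpha(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        d = design_2x2((5, 5, 5, 5))
        X = build_design(d).to_numpy(dtype=float)
        s = np.exp(rng.normal(0, 0.2, 20))
        mu = s * 200 * 2 ** (X @ np.array([0.0, -0.7, 0.3, 1.1]))
        y = rng.poisson(mu).astype(float)
        res = irls_fit(y, X, s, 1e-8)
        oracle = statsmodels.GLM(y, X, family=statsmodels.families.Poisson(),
                                 offset=np.log(s)).fit()
        np.testing.assert_allclose(res.beta, oracle.params, atol=1e-4)
        np.testing.assert_allclose(np.sqrt(np.diag(res.cov)), oracle.bse,
                                   rtol=1e-3)

    def test_separation_is_clamped_not_divergent(self):
        d = design_2x2((2, 2, 2, 2))
        X = build_design(d).to_numpy(dtype=float)
        y = np.array([100, 110, 0, 0, 90, 95, 105, 100], dtype=float)
        res = irls_fit(y, X, np.ones(8), 0.05)
        assert res.clamped
        assert np.all(np.abs(res.beta) <= nb_glm.BETA_CLAMP + 1e-9)


class TestDispersionEstimation:
    def test_recovers_generating_dispersion(self):
        rng = np.random.default_rng(21)
        n = 200
        X = np.ones((n, 1))
        alpha = 0.1
        r = 1.0 / alpha
        mu = 500.0
        y = rng.negative_binomial(r, r / (r + mu), size=n).astype(float)
        est, boundary = profile_dispersion_mle(y, X, np.ones(n))
        assert not boundary
        assert 0.07 <= est <= 0.14

    def test_underdispersed_data_hits_lower_boundary(self):
        d = design_2x2((3, 3, 3, 3))
        X = build_design(d).to_numpy(dtype=float)
        y = np.repeat([10.0, 200.0, 50.0, 100.0], 3)
        est, boundary = profile_dispersion_mle(y, X, np.ones(12))
        assert boundary
        assert est < 5e-8

    def test_agrees_with_dense_grid_search(self):
        rng = np.random.default_rng(22)
        d = design_2x2((4, 4, 4, 4))
        X = build_design(d).to_numpy(dtype=float)
        r = 1 / 0.2
        mu = 300.0
        y = rng.negative_binomial(r, r / (r + mu), size=16).astype(float)
        s = np.ones(16)
        est, _ = profile_dispersion_mle(y, X, s)
        grid = np.exp(np.linspace(np.log(1e-8), np.log(10), 1000))
        lls = [irls_fit(y, X, s, a).loglik for a in grid]
        best = grid[int(np.argmax(lls))]
        assert est == pytest.approx(best, rel=0.05)  # 2 significant digits


class TestFitTrend:
    def test_noiseless_recovery(self):
        mu = np.linspace(10, 5000, 300)
        alpha = 2.0 / mu + 0.05
        model = fit_trend(mu, alpha)
        assert model.a1 == pytest.approx(2.0, rel=1e-6)
        assert model.a0 == pytest.approx(0.05, rel=1e-6)

    def test_constant_dispersion(self):
        mu = np.linspace(10, 5000, 200)
        model = fit_trend(mu, np.full(200, 0.1))
        assert model.a0 == pytest.approx(0.1, abs=1e-6)
        assert model.a1 == pytest.approx(0.0, abs=1e-3)

    def test_few_genes_fall_back_to_constant(self):
        mu = np.linspace(100, 1000, 10)
        model = fit_trend(mu, np.full(10, 0.2))
        assert model.a1 == 0.0
        assert model.a0 == pytest.approx(0.2)


class TestMapDispersion:
    def setup_method(self):
        rng = np.random.default_rng(23)
        self.d = design_2x2((4, 4, 4, 4))
        self.X = build_design(self.d).to_numpy(dtype=float)
        r = 1 / 0.15
        self.y = rng.negative_binomial(r, r / (r + 400.0), size=16).astype(float)
        self.s = np.ones(16)

    def test_flat_prior_limit_is_mle(self):
        mle, _ = profile_dispersion_mle(self.y, self.X, self.s)
        amap, _ = map_dispersion(self.y, self.X, self.s, 0.01, prior_var=1e6)
        assert amap == pytest.approx(mle, rel=0.01)

    def test_degenerate_prior_limit_is_trend(self):
        amap, _ = map_dispersion(self.y, self.X, self.s, 0.33, prior_var=1e-6)
        assert amap == pytest.approx(0.33, rel=0.01)

    def test_prior_at_likelihood_mode_changes_nothing(self):
        mle, _ = profile_dispersion_mle(self.y, self.X, self.s)
        amap, _ = map_dispersion(self.y, self.X, self.s, mle, prior_var=0.5)
        assert amap == pytest.approx(mle, rel=0.02)


class TestWald:
    def test_zero_effect_p_is_one(self):
        _, p = wald_test(0.0, 1.0)
        assert p == pytest.approx(1.0)

    def test_critical_z_gives_five_percent(self):
        _, p = wald_test(1.959964, 1.0)
        assert p == pytest.approx(0.05, rel=1e-4)

    def test_sign_symmetry(self):
        assert wald_test(0.7, 0.2)[1] == wald_test(-0.7, 0.2)[1]

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestLrt:
    def test_multiplicative_pattern_gives_null_statistic(self):
        # group means 100/200/50/100 are exactly multiplicative, so the
        # reduced model saturates the pattern and the LRT is 0
        d = design_2x2((2, 2, 2, 2))
        X = build_design(d).reindex(d.table.index).to_numpy(dtype=float)
        means = {("reference", "deletion"): 100, ("stress", "deletion"): 200,
                 ("reference", "wildtype"): 50, ("stress", "wildtype"): 100}
        y = np.array([float(means[(c, g)]) for c, g in
                      zip(d.table["condition"], d.table["genotype"])])
        stat, p, ok = lrt_interaction(y, X, X[:, :3], np.ones(8), 0.1)
        assert ok
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_asymptotic_agreement_with_wald(self):
        # at generous replication, LRT statistic ~ Wald z^2 for beta3
        rng = np.random.default_rng(31)
        d = design_2x2((20, 20, 20, 20))
        X = build_design(d).to_numpy(dtype=float)
        alpha = 0.05
        r = 1.0 / alpha
        rel = []
        for _ in range(100):
            beta = np.array([np.log(300), 0.3, -0.2, rng.normal(0, 0.3)])
            mu = np.exp(X @ beta)
            y = rng.negative_binomial(r, r / (r + mu)).astype(float)
            fit = irls_fit(y, X, np.ones(80), alpha)
            z2 = (fit.beta[3] ** 2) / fit.cov[3, 3]
            stat, _, _ = lrt_interaction(y, X, X[:, :3], np.ones(80), alpha)
            if stat > 0.5:  # relative agreement is meaningless near zero
                rel.append(abs(stat - z2) / stat)
        assert np.median(rel) < 0.15


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.02]), [0.02])

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        assert np.isfinite(out[[0, 2]]).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_oracle(self, pvals):
        m = len(pvals)
        # brute-force step-up definition: sort, take suffix minima of m*p/rank
        order = sorted(range(m), key=lambda i: pvals[i])
        sorted_p = [pvals[i] for i in order]
        adj_sorted = [min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
                      for i in range(m)]
        expected = [0.0] * m
        for pos, i in enumerate(order):
            expected[i] = adj_sorted[pos]
        np.testing.assert_allclose(bh_adjust(pvals), expected, rtol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(deadline=None, max_examples=100)
    def test_dominates_raw_p(self, pvals):
        out = bh_adjust(pvals)
        assert (out >= np.asarray(pvals) - 1e-15).all()
        assert (out <= 1.0).all()


class TestFitAll:
    def test_contrast_identities_exact(self, small_fit):
        fit, _ = small_fit
        ok = fit[fit["status"] == "ok"]
        np.testing.assert_allclose(ok["log2fc_wt"], ok["beta1"] + ok["beta3"],
                                   atol=1e-10)
        np.testing.assert_allclose(ok["log2fc_del"], ok["beta1"], atol=1e-10)

    def test_lrt_statistics_nonnegative(self, small_fit):
        fit, _ = small_fit
        assert (fit["lrt_stat"].dropna() >= 0).all()

    def test_padj_dominates_p(self, small_fit):
        fit, _ = small_fit
        for fam, src in [("padj_wt", "wald_p_wt"), ("padj_del", "wald_p_del"),
                         ("padj_interaction", "lrt_p")]:
            both = fit[[fam, src]].dropna()
            assert (both[fam] >= both[src] - 1e-12).all()

    def test_all_zero_gene_excluded_from_testing(self):
        d = design_2x2((2, 2, 2, 2))
        rng = np.random.default_rng(9)
        arr = rng.integers(50, 200, size=(30, 8))
        arr[5] = 0
        counts = CountMatrix(make_counts(arr, libs=list(d.table.index)))
        fit = fit_all(counts, d, FitConfig(exclude_genes=()))
        assert fit.loc["g5", "status"] == "all_zero"
        assert np.isnan(fit.loc["g5", "padj_interaction"])

    def test_single_gene_effect_recovery(self):
        # one strongly repressed gene among stable background genes
        rng = np.random.default_rng(17)
        d = design_2x2((4, 3, 3, 3))
        X = build_design(d).reindex(d.table.index).to_numpy(dtype=float)
        n_bg = 60
        alpha = 0.01
        r = 1 / alpha
        bg_mu = rng.uniform(200, 2000, size=n_bg)
        rows = [rng.negative_binomial(r, r / (r + m), size=13) for m in bg_mu]
        beta = np.array([np.log(5000.0), -0.5 * LN2, 0.0, -2.7 * LN2])
        mu = np.exp(X @ beta)
        rows.append(rng.negative_binomial(r, r / (r + mu)))
        counts = CountMatrix(make_counts(np.array(rows), libs=list(d.table.index)))
        fit = fit_all(counts, d, FitConfig(exclude_genes=()))
        assert fit.loc[f"g{n_bg}", "log2fc_wt"] == pytest.approx(-3.2, abs=0.5)
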