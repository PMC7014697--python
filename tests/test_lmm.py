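import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from hapscan import (
    EigenSystem,
    FitCounter,
    UnitDesign,
    explained_variance,
    fit_null,
    profile_h2,
    simulate_phenotype,
    transform,
    unified_f_test,
    wls_fit,
)
from hapscan.lmm import RankDeficientDesign, TransformedData
from hapscan.lmm import test_unit_emmax as emmax_unit_test
from hapscan.lmm import test_unit_exact as exact_unit_test
from hapscan.simulate import SimSpec


def identity_eig(n):
    return EigenSystem(values=np.ones(n), vectors=np.eye(n))


def make_td(y, eig):
    return transform(np.asarray(y, dtype=float), eig)


def unit_of(cols, kind="snp", unit_id="u"):
    cols = np.atleast_2d(np.asarray(cols, dtype=float))
    if cols.shape[0] == 1:
        cols = cols.T
    return UnitDesign(unit_id, kind, cols, cols.shape[1], "1", (1, 1))


def gls_oracle(y, X, K, h2):
    """Direct generalized least squares on the original scale."""
    n = len(y)
    V = (h2 / (1 - h2)) * K + np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    rss = float(resid @ Vi @ resid)
    nll = n * np.log(rss / (n - 1)) + float(np.linalg.slogdet(V)[1])
    return beta, rss, nll


class TestTransform:
    def test_identity_eigenvectors_leave_y_unchanged(self, rng):
        y = rng.normal(size=6)
        td = make_td(y, identity_eig(6))
        np.testing.assert_allclose(td.y_t, y)
        np.testing.assert_allclose(td.intercept_t, np.ones(6))

    def test_rotation_preserves_norm_and_inverts(self, sim_panel, rng):
        eig = sim_panel["eig"]
        y = rng.normal(size=eig.n)
        td = make_td(y, eig)
        assert abs(np.linalg.norm(td.y_t) - np.linalg.norm(y)) < 1e-8
        np.testing.assert_allclose(eig.vectors @ td.y_t, y, atol=1e-10)

    def test_dimension_mismatch(self, sim_panel):
        with pytest.raises(ValueError, match="length"):
            make_td(np.zeros(5), sim_panel["eig"])


class TestWLSFit:
    def test_h2_zero_is_ordinary_least_squares(self, rng):
        n = 30
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        td = make_td(y, identity_eig(n))
        fit = wls_fit(td, X, 0.0)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-10)
        rss_ols = float(np.sum((y - X @ beta_ols) ** 2))
        assert abs(fit.rss_weighted - rss_ols) < 1e-10

    @pytest.mark.parametrize("df_beta", [1, 3])
    @pytest.mark.parametrize("h2", [0.2, 0.5, 0.85])
    def test_matches_dense_gls_oracle(self, rng, df_beta, h2):
        n = 12
        A = rng.normal(size=(n, n))
        K = A @ A.T / n
        from hapscan import spectral_decompose
        eig = spectral_decompose(K)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, df_beta))])
        td = make_td(y, eig)
        X_t = eig.vectors.T @ X
        fit = wls_fit(td, X_t, h2)
        beta_o, rss_o, nll_o = gls_oracle(y, X, K, h2)
        np.testing.assert_allclose(fit.beta, beta_o, atol=1e-8)
        assert abs(fit.rss_weighted - rss_o) < 1e-8
        # -2logL defined up to an additive constant: compare differences
        fit2 = wls_fit(td, X_t, h2 / 2)
        _, _, nll_o2 = gls_oracle(y, X, K, h2 / 2)
        assert abs((fit.neg2loglik - fit2.neg2loglik) - (nll_o - nll_o2)) < 1e-8

    def test_perfect_fit_gives_zero_rss(self, rng):
        n = 10
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 + 3.0 * x
        td = make_td(y, identity_eig(n))
        fit = wls_fit(td, X, 0.3)
        assert fit.rss_weighted < 1e-18

    def test_rank_deficiency_names_column(self, rng):
        n = 15
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        td = make_td(rng.normal(size=n), identity_eig(n))
        with pytest.raises(RankDeficientDesign) as exc:
            wls_fit(td, X, 0.1)
        assert exc.value.column_index == 2


class TestProfileH2:
    def test_matches_dense_grid_minimum(self, sim_panel):
        eig = sim_panel["eig"]
        spec = SimSpec(n_samples=200, n_snps=400, seed=7, h2_poly=0.5)
        y, _ = simulate_phenotype(sim_panel["G"], spec, eig=eig)
        td = transform(y, eig)
        X_t = td.intercept_t[:, None]
        h2_opt, fit = profile_h2(td, X_t, tol=1e-4)
        grid = np.linspace(1e-6, 1 - 1e-6, 10001)
        nlls = [wls_fit(td, X_t, g).neg2loglik for g in grid]
        assert fit.neg2loglik <= min(nlls) + 1e-8

    def test_recovers_moderate_heritability_roughly(self, sim_panel):
        eig = sim_panel["eig"]
        est = []
        for seed in range(12):
            spec = SimSpec(n_samples=200, n_snps=400, seed=100 + seed, h2_poly=0.5)
            y, _ = simulate_phenotype(sim_panel["G"], spec, eig=eig)
            est.append(fit_null(transform(y, eig)).h2_genomic)
        assert 0.3 < np.mean(est) < 0.7

    def test_pure_noise_estimates_near_zero(self, sim_panel, rng):
        eig = sim_panel["eig"]
        est = []
        for _ in range(12):
            y = rng.normal(size=eig.n)
            est.append(fit_null(transform(y, eig)).h2_genomic)
        assert np.median(est) < 0.1

    def test_constant_phenotype_rejected(self, sim_panel):
        with pytest.raises(ValueError, match="constant"):
            fit_null(transform(np.ones(sim_panel["eig"].n), sim_panel["eig"]))


class TestUnifiedF:
    def test_matches_whitened_two_model_f(self, sim_panel, rng):
        eig = sim_panel["eig"]
        n = eig.n
        h2 = 0.4
        for df in (1, 4):
            y = rng.normal(size=n)
            td = make_td(y, eig)
            cols = rng.normal(size=(n, df))
            X_t = np.column_stack([td.intercept_t, eig.vectors.T @ cols])
            fit1 = wls_fit(td, X_t, h2)
            fit0 = wls_fit(td, td.intercept_t[:, None], h2)
            F, p = unified_f_test(fit0, fit1, n, df)
            # independent route: whitened variables y* = W^-1/2 y~, X* = W^-1/2 X~
            w = (h2 / (1 - h2)) * eig.values + 1
            ys, Xs = td.y_t / np.sqrt(w), X_t / np.sqrt(w)[:, None]
            full = sm.OLS(ys, Xs).fit()
            null = sm.OLS(ys, Xs[:, :1]).fit()
            df_eps = n - df - 1
            F_sm = (null.ssr - full.ssr) / df / (full.ssr / df_eps)
            assert abs(F - F_sm) < 1e-8
            assert abs(p - stats.f.sf(F_sm, df, df_eps)) < 1e-10

    def test_mismatched_h2_rejected(self, sim_panel, rng):
        eig = sim_panel["eig"]
        td = make_td(rng.normal(size=eig.n), eig)
        f0 = wls_fit(td, td.intercept_t[:, None], 0.3)
        f1 = wls_fit(td, td.intercept_t[:, None], 0.4)
        with pytest.raises(ValueError, match="different h2"):
            unified_f_test(f0, f1, eig.n, 1)

    def test_null_pvalues_uniform(self, sim_panel, rng):
        eig = sim_panel["eig"]
        n = eig.n
        spec = SimSpec(n_samples=n, n_snps=400, seed=33, h2_poly=0.5)
        pvals = []
        for rep in range(6):
            y, _ = simulate_phenotype(
                sim_panel["G"], SimSpec(n_samples=n, n_snps=400, seed=33 + rep, h2_poly=0.5),
                eig=eig,
            )
            td = transform(y, eig)
            h2 = fit_null(td).h2_genomic
            fit0 = wls_fit(td, td.intercept_t[:, None], h2)
            for _ in range(80):
                x = (rng.random(n) < 0.3).astype(float)
                r = emmax_unit_test(td, unit_of(x), eig, h2, null_fit_at_h2=fit0)
                pvals.append(r.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestUnitTests:
    def test_identity_kinship_reduces_to_classical_regression(self, rng):
        n = 40
        eig = identity_eig(n)
        x = (rng.random(n) < 0.4).astype(float)
        y = 0.3 * x + rng.normal(size=n)
        td = make_td(y, eig)
        h2 = fit_null(td).h2_genomic
        r = exact_unit_test(td, unit_of(x), eig, h2)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(r.p - ols.f_pvalue) < 1e-10

    def test_emmax_single_fit_per_unit(self, sim_panel, rng):
        eig = sim_panel["eig"]
        td = make_td(rng.normal(size=eig.n), eig)
        fit0 = wls_fit(td, td.intercept_t[:, None], 0.4)
        counter = FitCounter()
        for _ in range(10):
            x = (rng.random(eig.n) < 0.3).astype(float)
            emmax_unit_test(td, unit_of(x), eig, 0.4, null_fit_at_h2=fit0,
                            counter=counter)
        assert counter.count == 10

    def test_emmax_close_to_exact_for_null_units(self, sim_panel, rng):
        eig = sim_panel["eig"]
        y, _ = simulate_phenotype(
            sim_panel["G"], SimSpec(n_samples=eig.n, n_snps=400, seed=55, h2_poly=0.5),
            eig=eig,
        )
        td = transform(y, eig)
        h2 = fit_null(td).h2_genomic
        fit0 = wls_fit(td, td.intercept_t[:, None], h2)
        gaps = []
        for _ in range(40):
            x = (rng.random(eig.n) < 0.3).astype(float)
            u = unit_of(x)
            pe = emmax_unit_test(td, u, eig, h2, null_fit_at_h2=fit0).p
            px = exact_unit_test(td, u, eig, h2).p
            gaps.append(abs(np.log10(pe) - np.log10(px)))
        assert np.median(gaps) < 0.5

    def test_exact_equals_emmax_when_optimum_is_fixed_point(self, rng):
        # K = I makes the h2 profile flat, so any fixed h2 is an optimum
        n = 30
        eig = identity_eig(n)
        x = (rng.random(n) < 0.5).astype(float)
        y = x + rng.normal(size=n)
        td = make_td(y, eig)
        re = exact_unit_test(td, unit_of(x), eig, 0.5)
        rf = emmax_unit_test(td, unit_of(x), eig, re.h2_used)
        assert abs(re.p - rf.p) < 1e-12

    def test_invariant_under_eigenpair_permutation(self, sim_panel, rng):
        eig = sim_panel["eig"]
        perm = rng.permutation(eig.n)
        eig_p = EigenSystem(values=eig.values[perm], vectors=eig.vectors[:, perm])
        y, _ = simulate_phenotype(
            sim_panel["G"], SimSpec(n_samples=eig.n, n_snps=400, seed=77, h2_poly=0.4),
            eig=eig,
        )
        x = sim_panel["G"].calls[:, 10].astype(float)
        r1 = exact_unit_test(transform(y, eig), unit_of(x), eig, 0.4)
        r2 = exact_unit_test(transform(y, eig_p), unit_of(x), eig_p, 0.4)
        assert abs(r1.p - r2.p) < 1e-10

    def test_kinship_rescaling_absorbed_by_h2(self, sim_panel, rng):
        # at mapped heritabilities h/(1-h) = c h'/(1-h'), the statistic is
        # exactly invariant to K -> cK
        from hapscan import spectral_decompose
        eig = sim_panel["eig"]
        c = 3.0
        eig_c = spectral_decompose(c * sim_panel["K"].K)
        y, _ = simulate_phenotype(
            sim_panel["G"], SimSpec(n_samples=eig.n, n_snps=400, seed=88, h2_poly=0.4),
            eig=eig,
        )
        x = sim_panel["G"].calls[:, 20].astype(float)
        h2 = 0.45
        r = h2 / (1 - h2) / c
        h2_c = r / (1 + r)
        p1 = emmax_unit_test(transform(y, eig), unit_of(x), eig, h2).p
        p2 = emmax_unit_test(transform(y, eig_c), unit_of(x), eig_c, h2_c).p
        assert abs(p1 - p2) < 1e-10
        # the profiled version agrees up to optimizer tolerance
        x1 = exact_unit_test(transform(y, eig), unit_of(x), eig, 0.5)
        x2 = exact_unit_test(transform(y, eig_c), unit_of(x), eig_c, 0.5 / (0.5 + c / 2))
        assert abs(np.log10(x1.p) - np.log10(x2.p)) < 1e-2


class TestExplainedVariance:
    def test_zero_effect_zero_variance(self, rng):
        u = unit_of((rng.random(20) < 0.5).astype(float))
        assert explained_variance(np.zeros(1), u, rng.normal(size=20)) == 0.0

    def test_noise_free_phenotype_is_fully_explained(self, rng):
        x = (rng.random(25) < 0.5).astype(float)
        u = unit_of(x)
        y = 1.5 * x - 0.2
        assert abs(explained_variance(np.array([1.5]), u, y) - 100.0) < 1e-9

    def test_matches_r2_under_ols(self, rng):
        n = 60
        x = (rng.random(n) < 0.4).astype(float)
        y = 0.8 * x + rng.normal(size=n)
        td = make_td(y, identity_eig(n))
        r = exact_unit_test(td, unit_of(x), identity_eig(n), 0.3)
        r2 = sm.OLS(y, sm.add_constant(x)).fit().rsquared
        assert abs(r.explained_var_pct - 100 * r2) < 1e-6
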