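"""IV estimator checks against closed-form oracles and summary-MR toy sets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import assortmr as am
from assortmr.estimators import IdentificationError, IVFit, fit_2sls


def _oracle_2sls(y, X, Z):
    """Independent textbook 2SLS via explicit projection matrices."""
    Pz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    beta = np.linalg.solve(X.T @ Pz @ X, X.T @ Pz @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (len(y) - X.shape[1])
    cov = s2 * np.linalg.inv(X.T @ Pz @ X)
    return beta, cov


class TestFit2sls:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        z = rng.normal(size=(n, 3))
        x = z @ [0.6, 0.3, 0.1] + rng.normal(size=n)
        w = rng.normal(size=n)  # exogenous covariate
        y = 1.5 * x - 0.5 * w + rng.normal(size=n)
        fit = fit_2sls(y, x, z, exog=w)
        X = np.column_stack([x, w, np.ones(n)])
        Z = np.column_stack([z, w, np.ones(n)])
        beta, cov = _oracle_2sls(y, X, Z)
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)
        np.testing.assert_allclose(fit.cov, cov, atol=1e-8)

    def test_just_identified_equals_covariance_ratio(self):
        rng = np.random.default_rng(7)
        n = 200
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        fit = fit_2sls(y, x, z)
        iv = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
        assert fit.params[0] == pytest.approx(iv, abs=1e-8)

    def test_exact_linear_system(self):
        z = np.array([0.0, 1.0, 2.0, 3.0])
        x = z.copy()
        y = 2 * x
        fit = fit_2sls(y, x, z)
        assert fit.params[0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(fit.resid, 0, atol=1e-12)

    def test_instrumenting_with_exposure_equals_ols(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        fit = fit_2sls(y, x, x)
        ols = np.polyfit(x, y, 1)[0]
        assert fit.params[0] == pytest.approx(ols, abs=1e-10)

    def test_under_identified_raises(self):
        rng = np.random.default_rng(9)
        n = 30
        x = rng.normal(size=(n, 2))
        with pytest.raises(IdentificationError):
            fit_2sls(rng.normal(size=n), x, rng.normal(size=(n, 1)))

    def test_duplicate_instruments_raise(self):
        rng = np.random.default_rng(10)
        n = 40
        z = rng.normal(size=n)
        with pytest.raises(IdentificationError):
            fit_2sls(rng.normal(size=n), rng.normal(size=(n, 2)),
                     np.column_stack([z, z]))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_oracle_agreement_property(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 50)
        k_iv = rng.integers(1, 4)
        z = rng.normal(size=(n, k_iv))
        x = z @ rng.normal(size=k_iv) + rng.normal(size=n)
        y = rng.normal() * x + rng.normal(size=n)
        fit = fit_2sls(y, x, z)
        X = np.column_stack([x, np.ones(n)])
        Z = np.column_stack([z, np.ones(n)])
        beta, cov = _oracle_2sls(y, X, Z)
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)


class TestTrioTSLS:
    def test_tsls1_equals_wald_ratio_with_single_instrument(self, random_mating_trios):
        trios = random_mating_trios
        w = am.estimate_weights(trios)
        sc = am.build_scores(trios, w)
        r1 = am.mr_tsls1(sc, trios)
        rows = sc.rows
        ratio = (np.cov(sc.s, trios.y[rows])[0, 1] /
                 np.cov(sc.s, trios.x[rows])[0, 1])
        assert r1.estimate == pytest.approx(ratio, abs=1e-8)

    def test_all_methods_recover_causal_effect_random_mating(self, random_mating_trios):
        trios = random_mating_trios
        w = am.estimate_weights(trios)
        sc = am.build_scores(trios, w)
        for fn in (am.mr_tsls1, am.mr_tsls2, am.mr_tsls3):
            r = fn(sc, trios)
            assert abs(r.estimate - 0.1) < 3 * r.se

    def test_tsls2_constant_parental_scores_unidentified(self, random_mating_trios):
        trios = random_mating_trios
        w = am.estimate_weights(trios)
        sc = am.build_scores(trios, w)
        bad = am.ScoreSet(rows=sc.rows, s=sc.s,
                          s_m=np.zeros_like(sc.s_m), s_f=np.zeros_like(sc.s_f),
                          w_m=sc.w_m, w_f=sc.w_f)
        with pytest.raises(IdentificationError):
            am.mr_tsls2(bad, trios)

    def test_tsls3_duplicate_instruments_unidentified(self, random_mating_trios):
        trios = random_mating_trios
        w = am.estimate_weights(trios)
        sc = am.build_scores(trios, w)
        bad = am.ScoreSet(rows=sc.rows, s=sc.s, s_m=sc.s_m, s_f=sc.s_f,
                          w_m=sc.s.copy(), w_f=sc.s.copy())
        with pytest.raises(IdentificationError):
            am.mr_tsls3(bad, trios)

    def test_assortment_test_reported_with_direction(self, small_trios):
        w = am.estimate_weights(small_trios)
        sc = am.build_scores(small_trios, w)
        r = am.mr_tsls2(sc, small_trios)
        assert r.assort_df == 2
        assert 0 <= r.assort_p <= 1
        # signed parental coefficients exposed for directionality
        assert "score_m" in r.aux and "score_f" in r.aux
        # strong cross-trait assortment in this fixture: test should fire
        assert r.assort_p < 0.05

    def test_ci_and_p_value_consistency(self, random_mating_trios):
        trios = random_mating_trios
        w = am.estimate_weights(trios)
        sc = am.build_scores(trios, w)
        r = am.mr_tsls1(sc, trios)
        lo, hi = r.ci
        assert lo == pytest.approx(r.estimate - 1.96 * r.se, abs=1e-3 * r.se)
        assert (r.p_value < 0.05) == r.ci_excludes(0.0)


class TestSummaryStats:
    def test_betax_matches_weights(self, random_mating_trios):
        trios = random_mating_trios
        w = am.estimate_weights(trios, half="B")
        stats_ = am.snp_summary_stats(trios, half="B")
        np.testing.assert_allclose(stats_.beta_x, w.weights, atol=1e-10)

    def test_round_trip_frame(self, random_mating_trios):
        stats_ = am.snp_summary_stats(random_mating_trios)
        back = am.SummaryStats.from_frame(stats_.to_frame())
        np.testing.assert_allclose(back.beta_y, stats_.beta_y)

    def test_permuted_outcome_null_betas(self, random_mating_trios, rng):
        trios = random_mating_trios
        shuffled = am.TrioDataset(
            g_o=trios.g_o, g_m=trios.g_m, g_f=trios.g_f, nt_m=trios.nt_m,
            nt_f=trios.nt_f, x=trios.x, y=rng.permutation(trios.y),
            x_m=trios.x_m, x_f=trios.x_f, split_a=trios.split_a,
            instrument_snps=trios.instrument_snps)
        stats_ = am.snp_summary_stats(shuffled)
        se = stats_.beta_y.std(ddof=1) / np.sqrt(stats_.n_snps)
        assert abs(stats_.beta_y.mean()) < 3 * se + 1e-3


def _toy_stats(bx, by, se_y=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.ones_like(bx) if se_y is None else np.asarray(se_y, dtype=float)
    return am.SummaryStats(snp_id=np.arange(len(bx)), beta_x=bx,
                           se_x=np.full(len(bx), 0.1), beta_y=by, se_y=se_y,
                           n_x=np.full(len(bx), 100), n_y=np.full(len(bx), 100))


class TestSummaryMR:
    def test_ivw_is_weighted_mean_of_ratios(self):
        # equal weights (bx=1, se_y=1), ratios {1, 3} -> ivw = 2
        s = _toy_stats([1, 1], [1, 3])
        r = am.summary_mr(s, "ivw")
        assert r.estimate == pytest.approx(2.0, abs=1e-12)
        assert r.se == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_ivw_single_snp_equals_wald_ratio(self):
        s1 = _toy_stats([0.5], [1.0])
        assert am.summary_mr(s1, "ivw").estimate == pytest.approx(2.0, abs=1e-12)
        s = _toy_stats([0.5, 2.0], [1.0, 4.0])
        ratios = s.beta_y / s.beta_x
        w = s.beta_x**2 / s.se_y**2
        expected = np.sum(w * ratios) / np.sum(w)
        assert am.summary_mr(s, "ivw").estimate == pytest.approx(expected, abs=1e-12)

    def test_egger_exact_line(self):
        # points exactly on y = 0.7 x => slope 0.7, intercept 0
        bx = np.array([0.5, 1.0, 1.5, 2.0])
        s = _toy_stats(bx, 0.7 * bx)
        r = am.summary_mr(s, "egger")
        assert r.estimate == pytest.approx(0.7, abs=1e-10)
        assert r.aux["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_egger_needs_three_snps(self):
        with pytest.raises(ValueError):
            am.summary_mr(_toy_stats([1, 1], [1, 2]), "egger")

    def test_weighted_median_outlier_robust(self):
        # equal weights, ratios {1, 2, 100} -> weighted median = 2
        s = _toy_stats([1, 1, 1], [1, 2, 100])
        r = am.summary_mr(s, "weighted_median", n_boot=50, seed=0)
        assert r.estimate == pytest.approx(2.0, abs=1e-10)

    def test_mbe_identical_ratios(self):
        s = _toy_stats([1, 1, 1], [1.3, 1.3, 1.3])
        r = am.summary_mr(s, "mbe", n_boot=20, seed=0)
        assert r.estimate == pytest.approx(1.3, abs=1e-10)

    def test_mbe_mode_of_cluster(self):
        # a tight cluster at 1 plus one outlier: mode near 1, not the mean
        s = _toy_stats([1] * 6, [0.98, 1.0, 1.02, 1.0, 0.99, 5.0])
        r = am.summary_mr(s, "mbe", n_boot=20, seed=0)
        assert abs(r.estimate - 1.0) < 0.1

    def test_zero_exposure_beta_excluded(self):
        s = _toy_stats([1.0, 0.0, 1.0], [1.0, 5.0, 3.0])
        with pytest.warns(RuntimeWarning, match="zero exposure"):
            r = am.summary_mr(s, "ivw")
        assert r.estimate == pytest.approx(2.0, abs=1e-12)


class TestHeterogeneity:
    def test_identical_ratios_give_zero_q(self):
        s = _toy_stats([0.5, 1.0, 1.5], [1.0, 2.0, 3.0])
        out = am.heterogeneity_tests(s)
        assert out["q"] == pytest.approx(0.0, abs=1e-12)
        assert out["q_p"] == pytest.approx(1.0)
        assert out["q_df"] == 2

    def test_q_null_rejection_rate(self):
        # homogeneous simulated null: Q rejects at ~ alpha
        rng = np.random.default_rng(3)
        n_rep, j = 400, 20
        rej = 0
        for _ in range(n_rep):
            bx = rng.uniform(0.5, 1.5, size=j)
            se_y = np.full(j, 0.05)
            by = 0.4 * bx + rng.normal(0, se_y)
            s = _toy_stats(bx, by, se_y)
            out = am.heterogeneity_tests(s)
            rej += out["q_p"] < 0.05
        rate = rej / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_score_correlation_detects_cross_trait_assortment(self, small_trios,
                                                              random_mating_trios):
        def xy_scores(trios):
            gx = trios.panel.gx
            gy = trios.panel.gy
            return (trios.g_o[:, gx].sum(axis=1).astype(float),
                    trios.g_o[:, gy].sum(axis=1).astype(float))

        sx, sy = xy_scores(small_trios)  # strong cross-trait assortment
        assert am.score_correlation_test(sx, sy)["p"] < 1e-4
        sx0, sy0 = xy_scores(random_mating_trios)
        assert am.score_correlation_test(sx0, sy0)["p"] > 0.001
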