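import numpy as np
import pandas as pd
import pytest

import lcrclim as lc
from lcrclim.degree_days import PiecewiseSpec
from lcrclim.panel_model import (FitResult, _control_columns, _slope_columns,
                                 cluster_covariance)


def make_fit(knots, beta, gamma=(0.0, 0.0), cov=None):
    return FitResult(cause="total", knots=knots,
                     beta=np.asarray(beta, dtype=float),
                     gamma=np.asarray(gamma, dtype=float),
                     cov_slopes=np.eye(5) if cov is None else cov,
                     params=pd.Series(dtype=float), r2=np.nan,
                     r2_within=np.nan, sse=np.nan, n=0, n_clusters=0)


def random_panel(n_counties=6, n_years=8, n_states=2, seed=0):
    """Small random panel with all columns the estimator needs."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_counties):
        state = f"S{c % n_states}"
        for y in range(2001, 2001 + n_years):
            dd10 = rng.uniform(800, 2000)
            dd29 = rng.uniform(10, 80)
            dd38 = rng.uniform(0, 3)
            rows.append({
                "county_id": f"C{c}", "state_id": state, "year": y,
                "lcr_total": rng.uniform(0, 0.4),
                "dd_10": dd10, "dd_29": dd29, "dd_38": dd38,
                "prec_total": rng.uniform(300, 900),
            })
    return pd.DataFrame(rows)


class TestFitLcrModel:
    def test_zero_noise_recovers_truth_exactly(self, zero_noise_sim):
        cfg, weather, losses, liabilities, truth = zero_noise_sim
        panel = lc.build_lcr_panel(losses, liabilities, crop=cfg.crop)
        expo = lc.season_exposure(weather, cfg.season, [10, 29, 38])
        merged = lc.merge_exposures(panel, expo)
        fit = lc.fit_lcr_model(merged, lc.ModelSpec(knots=PiecewiseSpec(29, 38)))
        np.testing.assert_allclose(fit.beta, truth.beta, rtol=0, atol=1e-8)
        np.testing.assert_allclose(fit.gamma, truth.gamma, rtol=0, atol=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_dummy_ols_equals_partialled_ols(self):
        """Frisch-Waugh: slopes from the full dummy regression must equal
        slopes from regressing partialled y on partialled weather terms."""
        panel = random_panel()
        spec = lc.ModelSpec(knots=PiecewiseSpec(29, 38))
        fit = lc.fit_lcr_model(panel, spec)

        y = panel["lcr_total"].to_numpy()
        Xs = _slope_columns(panel, spec.knots)
        W, _ = _control_columns(panel, spec.trend_degree)
        # independent partialling path
        My = y - W @ np.linalg.lstsq(W, y, rcond=None)[0]
        MX = Xs - W @ np.linalg.lstsq(W, Xs, rcond=None)[0]
        slopes = np.linalg.lstsq(MX, My, rcond=None)[0]
        np.testing.assert_allclose(fit.slopes, slopes, rtol=0, atol=1e-10)

    def test_clustered_covariance_equals_brute_force(self):
        """Hand-assembled sandwich (X'X)^-1 (sum_g X_g'e_g e_g'X_g) (X'X)^-1
        with the G/(G-1)(n-1)/(n-k) factor, on a toy 4-cluster panel."""
        rng = np.random.default_rng(5)
        n, k = 40, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = rng.normal(size=n)
        groups = np.repeat(np.arange(4), n // 4)

        params = np.linalg.lstsq(X, y, rcond=None)[0]
        e = y - X @ params
        V = cluster_covariance(X, e, groups)

        xtx_inv = np.linalg.inv(X.T @ X)
        meat = np.zeros((k, k))
        for g in range(4):
            xg, eg = X[groups == g], e[groups == g]
            u = xg.T @ eg
            meat += np.outer(u, u)
        c = 4 / 3 * (n - 1) / (n - k)
        expected = c * xtx_inv @ meat @ xtx_inv
        np.testing.assert_allclose(V, expected, rtol=0, atol=1e-10)

    def test_clustered_covariance_matches_statsmodels(self, small_panel):
        """Independent library route: statsmodels' cluster-robust OLS
        covariance (same Stata-convention correction) must agree."""
        import statsmodels.api as sm

        spec = lc.ModelSpec(knots=PiecewiseSpec(29, 38))
        fit = lc.fit_lcr_model(small_panel, spec)

        y = small_panel["lcr_total"].to_numpy()
        Xs = _slope_columns(small_panel, spec.knots)
        W, _ = _control_columns(small_panel, spec.trend_degree)
        X = np.column_stack([Xs, W])
        res = sm.OLS(y, X).fit(cov_type="cluster",
                               cov_kwds={"groups": small_panel["year"]})
        np.testing.assert_allclose(fit.slopes, res.params[:5], atol=1e-10)
        np.testing.assert_allclose(fit.cov_slopes,
                                   res.cov_params()[:5, :5], rtol=1e-6)

    def test_covariance_symmetric_psd(self, small_panel):
        fit = lc.fit_lcr_model(small_panel, lc.ModelSpec(knots=PiecewiseSpec(29, 38)))
        V = fit.cov_slopes
        np.testing.assert_allclose(V, V.T, atol=1e-18)
        assert np.linalg.eigvalsh(V).min() >= -1e-18
        assert fit.n == len(small_panel)

    def test_invariant_to_row_order_and_relabeling(self):
        panel = random_panel(n_counties=4, n_years=5, seed=3)
        spec = lc.ModelSpec(knots=PiecewiseSpec(29, 38))
        base = lc.fit_lcr_model(panel, spec)

        shuffled = panel.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_s = lc.fit_lcr_model(shuffled, spec)
        np.testing.assert_allclose(fit_s.slopes, base.slopes, atol=1e-10)

        relabeled = panel.copy()
        relabeled["county_id"] = relabeled["county_id"].map(
            lambda c: f"Z{9 - int(c[1:])}")
        fit_r = lc.fit_lcr_model(relabeled, spec)
        np.testing.assert_allclose(fit_r.slopes, base.slopes, atol=1e-10)

    def test_year_fixed_effects_absorb_year_shocks(self):
        """With a large common year shock, dropping the year dummies must
        change the temperature slopes; keeping them recovers the truth."""
        cfg = lc.GeneratorConfig(n_states=3, counties_per_state=4,
                                 years=(2000, 2009), seed=21, noise_sd=0.0,
                                 county_effect_sd=0.0, year_effect_sd=0.08,
                                 base_lcr=0.4, dropout_rate=0.0)
        w = lc.generate_weather(cfg)
        losses, liabilities, truth = lc.generate_losses(w, cfg)
        assert truth.clamp_fraction == 0.0  # shock stays interior
        panel = lc.build_lcr_panel(losses, liabilities, crop=cfg.crop)
        merged = lc.merge_exposures(
            panel, lc.season_exposure(w, cfg.season, [10, 29, 38]))
        fit = lc.fit_lcr_model(merged, lc.ModelSpec(knots=PiecewiseSpec(29, 38)))
        np.testing.assert_allclose(fit.beta, truth.beta, atol=1e-8)

        # same regression without year dummies, assembled by hand
        y = merged["lcr_total"].to_numpy()
        Xs = _slope_columns(merged, PiecewiseSpec(29, 38))
        W, names = _control_columns(merged, 2)
        keep = [i for i, nm in enumerate(names) if not nm.startswith("year[")]
        X = np.column_stack([Xs, W[:, keep]])
        slopes_no_yfe = np.linalg.lstsq(X, y, rcond=None)[0][:3]
        assert np.abs(slopes_no_yfe - truth.beta).max() > 1e-6

    def test_single_state_panel_fits_without_trends(self):
        panel = random_panel(n_counties=3, n_years=4, n_states=1)
        fit = lc.fit_lcr_model(panel, lc.ModelSpec(knots=PiecewiseSpec(29, 38)))
        assert not any(ix.startswith("trend[") for ix in fit.params.index)

    def test_too_few_clusters_rejected(self):
        panel = random_panel(n_counties=3, n_years=1)
        with pytest.raises(ValueError):
            lc.fit_lcr_model(panel, lc.ModelSpec(knots=PiecewiseSpec(29, 38)))

    def test_requires_fixed_knots(self, small_panel):
        with pytest.raises(ValueError, match="fixed knots"):
            lc.fit_lcr_model(small_panel, lc.ModelSpec(knots=None))


class TestSearchKnots:
    def test_selected_knots_inside_search_windows(self, small_panel):
        fit = lc.search_knots(small_panel, lc.ModelSpec())
        assert 20 <= fit.knots.c1 <= 35
        assert 36 <= fit.knots.c2 <= 43

    def test_selected_r2_maximal_and_matches_full_refit(self, small_panel):
        fit = lc.search_knots(small_panel, lc.ModelSpec())
        cands = fit.candidates
        assert len(cands) == 16 * 8
        best = cands.loc[cands["sse"].idxmin()]
        assert (best["c1"], best["c2"]) == (fit.knots.c1, fit.knots.c2)
        assert (best["r2"] >= cands["r2"] - 1e-12).all()

        # the shortcut SSE must equal a full refit at a handful of candidates
        for _, row in cands.iloc[[0, 37, 101]].iterrows():
            refit = lc.fit_lcr_model(
                small_panel,
                lc.ModelSpec(knots=PiecewiseSpec(row["c1"], row["c2"])))
            assert refit.sse == pytest.approx(row["sse"], rel=1e-8)
        assert fit.sse == pytest.approx(cands["sse"].min(), rel=1e-8)

    def test_exact_ties_break_to_smallest_knots(self, small_panel):
        degenerate = small_panel.copy()
        degenerate["lcr_total"] = 0.0
        fit = lc.search_knots(degenerate, lc.ModelSpec())
        assert (fit.knots.c1, fit.knots.c2) == (20, 36)

    def test_empty_grid_rejected(self, small_panel):
        with pytest.raises(ValueError, match="grid"):
            lc.search_knots(small_panel, lc.ModelSpec(c1_grid=()))

    def test_grid_outside_windows_rejected(self):
        with pytest.raises(ValueError):
            lc.ModelSpec(c1_grid=(19,))
        with pytest.raises(ValueError):
            lc.ModelSpec(c2_grid=(44,))


class TestMarginalEffects:
    def test_below_and_at_first_cutoff_are_zero(self):
        fit = make_fit(PiecewiseSpec(29, 40), beta=(1e-3, 2e-3, 5e-3))
        assert lc.marginal_effect_day(fit, 5.0)[0] == 0.0
        assert lc.marginal_effect_day(fit, 10.0)[0] == 0.0

    def test_piecewise_hand_evaluation(self):
        fit = make_fit(PiecewiseSpec(29, 40), beta=(-0.0003, 0.001, 0.01))
        value, _ = lc.marginal_effect_day(fit, 35.0)
        assert value == pytest.approx(19 * -0.0003 + 6 * 0.001, abs=1e-12)

    def test_above_second_cutoff_uses_all_three_slopes(self):
        fit = make_fit(PiecewiseSpec(29, 40), beta=(-0.0003, 0.001, 0.01))
        value, _ = lc.marginal_effect_day(fit, 42.0)
        expected = 19 * -0.0003 + 11 * 0.001 + 2 * 0.01
        assert value == pytest.approx(expected, abs=1e-12)

    def test_delta_method_se(self):
        cov = np.diag([1e-8, 4e-8, 9e-8, 0, 0]).astype(float)
        fit = make_fit(PiecewiseSpec(29, 40), beta=(0, 0, 0), cov=cov)
        _, se = lc.marginal_effect_day(fit, 35.0)
        expected = np.sqrt(19**2 * 1e-8 + 6**2 * 4e-8)
        assert se == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_temperature_rejected(self):
        fit = make_fit(PiecewiseSpec(29, 40), beta=(0, 0, 0))
        with pytest.raises(ValueError):
            lc.marginal_effect_day(fit, 46.0)


class TestPrecipEffect:
    def test_no_change_is_zero(self):
        fit = make_fit(PiecewiseSpec(29, 40), beta=(0, 0, 0),
                       gamma=(-1e-4, 5e-8))
        assert lc.precip_effect(fit, 600.0, 600.0)[0] == 0.0

    def test_hand_arithmetic(self):
        fit = make_fit(PiecewiseSpec(29, 40), beta=(0, 0, 0),
                       gamma=(-1e-4, 5e-8))
        value, _ = lc.precip_effect(fit, 600.0, 660.0)
        assert value == pytest.approx(-1e-4 * 60 + 5e-8 * (660**2 - 600**2),
                                      abs=1e-12)

    def test_sign_flips_across_quadratic_minimum(self):
        gamma = (-1e-4, 5e-8)
        p_star = -gamma[0] / (2 * gamma[1])  # 1000 mm
        fit = make_fit(PiecewiseSpec(29, 40), beta=(0, 0, 0), gamma=gamma)
        below = lc.precip_effect(fit, p_star - 100, p_star - 50)[0]
        above = lc.precip_effect(fit, p_star + 50, p_star + 100)[0]
        assert below < 0 < above


class TestFitResultSerialization:
    def test_json_round_trip(self, tmp_path, small_panel):
        fit = lc.fit_lcr_model(small_panel, lc.ModelSpec(knots=PiecewiseSpec(29, 38)))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = FitResult.from_json(path)
        np.testing.assert_allclose(back.beta, fit.beta)
        np.testing.assert_allclose(back.cov_slopes, fit.cov_slopes)
        assert back.knots == fit.knots
        assert back.n_clusters == fit.n_clusters
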