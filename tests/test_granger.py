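import numpy as np
import pytest

from lamicsd import synth
from lamicsd.granger import (
    GCMatrix,
    adf_pvalues,
    autocov_sequence,
    compare_gc,
    conditional_gc,
    conditional_gc_ols,
    empirical_autocov,
    fit_var,
    reduced_model,
    select_order,
    stationarize,
)


def _var2_coupling(k=3, cross=0.4):
    c = np.zeros((k, k, 2))
    for i in range(k):
        c[i, i, 0] = 0.5
        c[i, i, 1] = -0.2
    c[1, 0, 0] = cross  # 0 -> 1
    c[2, 1, 0] = cross  # 1 -> 2
    return c


class TestStationarize:
    def test_differencing_shortens_by_one(self):
        x = np.random.default_rng(0).standard_normal((4, 3, 200))
        dx, report = stationarize(x)
        assert dx.shape == (4, 3, 199)
        assert set(report.columns) == {"adf_p", "stationary"}

    def test_random_walk_fails_then_passes(self):
        rng = np.random.default_rng(1)
        walk = np.cumsum(rng.standard_normal((1, 1, 3000)), axis=2)
        assert adf_pvalues(walk).iloc[0] > 0.05
        dx, report = stationarize(walk)
        assert report["stationary"].all()

    def test_stationary_ar1_passes_after_differencing(self):
        c = np.array([[[0.5]]])
        x = synth.generate_var_traces(c, n_trials=2, n_samples=2000, seed=2)
        _, report = stationarize(x)
        assert report["stationary"].all()

    def test_too_short_trials_rejected(self):
        with pytest.raises(ValueError):
            stationarize(np.zeros((1, 2, 30)))


class TestFitVar:
    def test_exact_recovery_of_deterministic_recursion(self):
        """A noise-free autoregressive recursion is identified exactly
        (a slowly decaying rotation keeps the trajectory well scaled)."""
        th = 2 * np.pi / 16  # whole rotation periods -> exactly zero mean
        A1 = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        x = np.empty((1, 2, 80))
        x[0, :, 0] = [1.0, 0.5]
        for t in range(1, 80):
            x[0, :, t] = A1 @ x[0, :, t - 1]
        m = fit_var(x, p=1)
        np.testing.assert_allclose(m.coefs[0], A1, atol=1e-8)
        assert np.abs(m.sigma).max() < 1e-12

    def test_consistency_on_long_realization(self):
        c = _var2_coupling()
        x = synth.generate_var_traces(c, n_trials=1, n_samples=100_000, seed=4)
        m = fit_var(x, p=2)
        truth = np.stack([c[:, :, 0], c[:, :, 1]])
        assert np.sqrt(np.mean((m.coefs - truth) ** 2)) < 0.01

    def test_trial_boundaries_respected(self):
        """Fitting two trials jointly must not regress across the trial
        boundary: a constructed pair where the boundary-crossing lag is
        wildly inconsistent gives a different fit than naive concatenation."""
        rng = np.random.default_rng(5)
        a = synth.generate_var_traces(
            np.array([[[0.8]]]), n_trials=1, n_samples=200, seed=6
        )
        b = -a + 0.01 * rng.standard_normal(a.shape)
        two_trials = np.concatenate([a, b], axis=0)
        concatenated = np.concatenate([a, b], axis=2)
        m_trials = fit_var(two_trials, p=1)
        m_concat = fit_var(concatenated, p=1)
        assert not np.allclose(m_trials.coefs, m_concat.coefs, atol=1e-4)

    def test_lwr_and_ols_agree_on_long_samples(self):
        c = _var2_coupling()
        x = synth.generate_var_traces(c, n_trials=1, n_samples=50_000, seed=7)
        m_ols = fit_var(x, p=2, method="ols")
        m_lwr = fit_var(x, p=2, method="lwr")
        np.testing.assert_allclose(m_ols.coefs, m_lwr.coefs, atol=5e-3)
        np.testing.assert_allclose(m_ols.sigma, m_lwr.sigma, atol=5e-3)

    def test_singular_input_rejected(self):
        x = np.zeros((2, 2, 100))
        with pytest.raises(ValueError):
            fit_var(x, p=1)


class TestSelectOrder:
    def test_var2_order_recovered(self):
        c = _var2_coupling()
        hits = 0
        for seed in range(30):
            x = synth.generate_var_traces(
                c, n_trials=4, n_samples=500, seed=100 + seed
            )
            hits += select_order(x, max_order=6) == 2
        assert hits >= 27  # >= 90% of runs

    def test_white_noise_aic_flat_within_penalty(self):
        """On white noise the fit term contributes almost nothing: AIC
        differences across orders stay within the parameter-count
        penalties themselves."""
        rng = np.random.default_rng(8)
        x = rng.standard_normal((4, 3, 500))
        k = 3
        aics = {}
        for p in range(1, 6):
            m = fit_var(x, p, offset=6)
            lndet = (
                np.linalg.slogdet(m.sigma)[1]
                + k * np.log((m.n_eff - k * p) / m.n_eff)
            )
            aics[p] = lndet + 2.0 * p * k * k / m.n_eff
        spread = max(aics.values()) - min(aics.values())
        max_penalty_gap = 2.0 * 5 * k * k / m.n_eff
        assert spread < 2 * max_penalty_gap

    def test_max_order_one(self):
        x = np.random.default_rng(9).standard_normal((2, 2, 300))
        assert select_order(x, max_order=1) == 1


class TestAutocovariance:
    def test_univariate_ar1_closed_form(self):
        phi, s2 = 0.6, 2.0
        from lamicsd.granger import VarModel

        model = VarModel(
            order=1,
            coefs=np.array([[[phi]]]),
            sigma=np.array([[s2]]),
            n_eff=1000,
            loglik=0.0,
            spectral_radius=phi,
        )
        gam = autocov_sequence(model, n_lags=5)
        for h in range(6):
            assert gam[h, 0, 0] == pytest.approx(
                s2 * phi**h / (1 - phi**2), rel=1e-10
            )

    def test_gamma0_symmetric_positive_definite(self):
        c = _var2_coupling()
        x = synth.generate_var_traces(c, n_trials=4, n_samples=800, seed=10)
        gam = autocov_sequence(fit_var(x, 2, method="lwr"), 10)
        g0 = gam[0]
        np.testing.assert_allclose(g0, g0.T, atol=1e-12)
        assert np.linalg.eigvalsh(g0).min() > 0

    def test_model_implied_matches_empirical_for_lwr_fit(self):
        """The Yule-Walker fit is moment-matching: its implied
        autocovariance reproduces the empirical sequence up to lag p."""
        c = _var2_coupling()
        x = synth.generate_var_traces(c, n_trials=3, n_samples=600, seed=11)
        model = fit_var(x, 2, method="lwr")
        implied = autocov_sequence(model, 2)
        empirical = empirical_autocov(x, 2)
        np.testing.assert_allclose(implied, empirical, atol=1e-10)

    def test_matches_long_simulation(self):
        c = _var2_coupling()
        x = synth.generate_var_traces(c, n_trials=1, n_samples=200_000, seed=12)
        model = fit_var(x, 2, method="lwr")
        gam = autocov_sequence(model, 4)
        emp = empirical_autocov(x, 4)
        assert np.abs(gam - emp).max() < 0.05 * np.abs(emp[0]).max()


class TestReducedModel:
    def test_identity_reduction_recovers_full_model(self):
        c = _var2_coupling()
        x = synth.generate_var_traces(c, n_trials=3, n_samples=600, seed=13)
        full = fit_var(x, 2, method="lwr")
        gam = autocov_sequence(full, 10)
        _, sigma = reduced_model(gam, [0, 1, 2], order=2)
        np.testing.assert_allclose(sigma, full.sigma, atol=1e-10)

    def test_independent_series_unaffected_by_removal(self):
        """Removing an independent series leaves the target's residual
        variance unchanged, so F = 0 exactly on the model-implied
        autocovariance of a diagonal system."""
        from lamicsd.granger import VarModel

        coefs = np.zeros((1, 3, 3))
        np.fill_diagonal(coefs[0], [0.5, 0.3, 0.7])
        model = VarModel(
            order=1, coefs=coefs, sigma=np.eye(3), n_eff=1000, loglik=0.0,
            spectral_radius=0.7,
        )
        gam = autocov_sequence(model, 6)
        _, sig_red = reduced_model(gam, [0, 1], order=1)
        assert sig_red[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert sig_red[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_agreement_with_ols_refit_on_long_data(self):
        """On long realizations of a densely coupled system (every ordered
        pair carries genuine causality) the Yule-Walker route and a direct
        pooled-OLS refit of the reduced regressions coincide."""
        c = np.zeros((4, 4, 2))
        c[:, :, 0] = [
            [0.3, 0.45, -0.35, 0.3],
            [0.5, 0.3, 0.45, -0.3],
            [-0.35, 0.45, 0.3, 0.45],
            [0.45, -0.35, 0.5, 0.3],
        ]
        c[:, :, 1] = -0.1 * np.eye(4)
        x = synth.generate_var_traces(c, n_trials=1, n_samples=200_000, seed=14)
        F_auto = conditional_gc(x, p=2).F
        F_ols = conditional_gc_ols(x, p=2)
        m = ~np.eye(4, dtype=bool)
        rel = np.abs(F_auto[m] - F_ols[m]) / np.abs(F_ols[m])
        assert rel.max() < 1e-3


class TestConditionalGC:
    def test_null_scale_matches_asymptotics(self):
        """Independent series: E[F] ~ p / (effective samples), and the
        95th percentile sits on the chi-squared scale."""
        null = np.zeros((3, 3, 2))
        for i in range(3):
            null[i, i, 0] = 0.5
            null[i, i, 1] = -0.2
        Fs = []
        for seed in range(60):
            x = synth.generate_var_traces(
                null, n_trials=5, n_samples=400, seed=3000 + seed
            )
            Fs.append(conditional_gc(x, p=2).F)
        Fs = np.array(Fs)
        m = ~np.eye(3, dtype=bool)
        n_eff = 5 * (400 - 2)
        scale = 2.0 / n_eff  # p lags per excluded source
        assert np.nanmean(Fs[:, m]) == pytest.approx(scale, rel=0.5)
        assert np.nanquantile(Fs[:, m], 0.95) < 6 * scale

    def test_chain_conditioning_property(self):
        """x -> y -> z: conditioning on y removes the indirect x -> z
        association while the direct links stay large."""
        chain = _var2_coupling(cross=0.4)
        hits = 0
        for seed in range(25):
            x = synth.generate_var_traces(
                chain, n_trials=10, n_samples=600, seed=seed
            )
            F = conditional_gc(x, p=2).F
            hits += (F[2, 0] < 0.005) and (F[1, 0] > 0.02) and (F[2, 1] > 0.02)
        assert hits >= 23

    def test_scale_invariance(self):
        c = _var2_coupling()
        x = synth.generate_var_traces(c, n_trials=4, n_samples=600, seed=15)
        F1 = conditional_gc(x, p=2).F
        y = x.copy()
        y[:, 1, :] *= 37.0
        F2 = conditional_gc(y, p=2).F
        m = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(F1[m], F2[m], atol=1e-8)

    def test_generator_preset_edge_detected(self, params_pre):
        x = synth.generate_var_traces(
            params_pre.var_coupling, n_trials=10, n_samples=800, seed=16
        )
        F = conditional_gc(x, p=2).F
        idx = {"I/II": 0, "III/IV": 1, "Vb": 2, "VI": 3}
        null_scale = 2.0 / (10 * 798)
        assert F[idx["VI"], idx["I/II"]] > 10 * null_scale

    def test_duplicate_target_conditioning_guard(self):
        """A (near-)copy of the target among the conditioning series means
        no source can add predictive power: F into the target collapses to
        the null scale.  An exact copy makes the moment matrices singular
        and raises a clear error instead of returning garbage."""
        c = np.array([[[0.5]]])
        x = synth.generate_var_traces(c, n_trials=2, n_samples=600, seed=17)
        near = x + 1e-4 * np.random.default_rng(1).standard_normal(x.shape)
        other = synth.generate_var_traces(c, n_trials=2, n_samples=600, seed=18)
        trip = np.concatenate([x, near, other], axis=1)
        gc = conditional_gc(trip, p=1)
        # source = series 2, target = series 0, conditioned on the copy
        assert gc.F[0, 2] < 1e-3
        exact = np.concatenate([x, x, other], axis=1)
        with pytest.raises(ValueError):
            conditional_gc(exact, p=1)


class TestCompareGC:
    def _gc_set(self, coupling, n_subjects, seed0):
        out = []
        for s in range(n_subjects):
            x = synth.generate_var_traces(
                coupling, n_trials=10, n_samples=600, seed=seed0 + s
            )
            out.append(conditional_gc(x, p=2))
        return out

    def test_identical_conditions_nothing_significant(self, params_pre):
        pre = self._gc_set(params_pre.var_coupling, 6, 500)
        post = self._gc_set(params_pre.var_coupling, 6, 900)
        cmp = compare_gc(pre, post)
        assert not cmp.table["significant"].any()

    def test_edited_edges_flagged_with_signs(self, params_pre, params_post):
        pre = self._gc_set(params_pre.var_coupling, 9, 40)
        post = self._gc_set(params_post.var_coupling, 9, 80)
        cmp = compare_gc(
            pre, post, layer_names=("I/II", "III/IV", "Vb", "VI")
        )
        tab = cmp.table
        assert tab.loc["I/II->VI", "significant"]
        assert tab.loc["I/II->VI", "direction"] == 1
        assert tab.loc["VI->Vb", "significant"]
        assert tab.loc["VI->Vb", "direction"] == 1
        assert tab.loc["Vb->III/IV", "significant"]
        assert tab.loc["Vb->III/IV", "direction"] == -1

    def test_unmatched_subjects_rejected(self, params_pre):
        pre = self._gc_set(params_pre.var_coupling, 3, 10)
        with pytest.raises(ValueError):
            compare_gc(pre, pre[:2])
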