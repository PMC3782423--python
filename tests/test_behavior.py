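"""Combination models, response likelihood, MLE fitting, model comparison
and the attraction-slope analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trajbayes as tb
from trajbayes.behavior import BeliefArrays, CombinationParams, combined_mean
from trajbayes.core import ConfigurationError, GaussianBelief


def synthetic_beliefs(rng, n=200):
    """Plausible per-trial belief arrays without running the full pipeline."""
    return BeliefArrays(
        mu_s=rng.uniform(0.3, 0.7, n),
        sigma_s=rng.uniform(0.03, 0.12, n),
        mu_d=rng.uniform(0.2, 0.8, n),
        sigma_d=np.exp(rng.uniform(np.log(0.01), np.log(0.12), n)),
    )


class TestCombinePrediction:
    def test_symmetric_precisions_average_the_means(self):
        stat = GaussianBelief(0.0, 1.0)
        dyn = GaussianBelief(1.0, 1.0, role="dynamic")
        out = tb.combine_prediction(stat, dyn, CombinationParams(1.0, 0.02, 0.0))
        assert out.mu == pytest.approx(0.5)
        assert out.sigma == pytest.approx(0.70711, abs=1e-5)

    def test_uninformative_dynamic_leaves_statistical_plus_bias(self):
        stat = GaussianBelief(0.4, 0.05)
        dyn = GaussianBelief(0.9, 1e6, role="dynamic")
        out = tb.combine_prediction(stat, dyn, CombinationParams(1.0, 0.02, 0.01))
        assert out.mu == pytest.approx(0.41, abs=1e-6)

    def test_unweighted_is_fixed_ratio_mixing(self):
        stat = GaussianBelief(0.2, 0.05)
        dyn = GaussianBelief(0.6, 0.02, role="dynamic")
        params = CombinationParams(0.25, 0.02, 0.0, "unweighted")
        assert tb.combine_prediction(stat, dyn, params).mu == pytest.approx(0.5)

    def test_select_chooses_more_precise_source(self):
        stat = GaussianBelief(0.3, 0.05)
        dyn = GaussianBelief(0.7, 0.1, role="dynamic")
        params = CombinationParams(1.0, 0.02, 0.0, "select")
        out = tb.combine_prediction(stat, dyn, params)
        assert out.mu == pytest.approx(0.3)
        assert out.sigma == pytest.approx(0.05)

    def test_m_range_depends_on_model(self):
        CombinationParams(1.8, 0.02, 0.0, "weighted")  # allowed
        with pytest.raises(ConfigurationError):
            CombinationParams(1.8, 0.02, 0.0, "unweighted")
        with pytest.raises(ConfigurationError):
            CombinationParams(-0.1, 0.02, 0.0, "weighted")

    @given(
        mu_s=st.floats(0.0, 1.0),
        mu_d=st.floats(0.0, 1.0),
        sg_s=st.floats(0.01, 0.5),
        sg_d=st.floats(0.01, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_optimal_weighting_is_bayes_fusion(self, mu_s, mu_d, sg_s, sg_d):
        """M=1, b=0: the combined belief is the posterior of two Gaussians —
        mean between the sources, spread below either."""
        out = tb.combine_prediction(
            GaussianBelief(mu_s, sg_s),
            GaussianBelief(mu_d, sg_d, role="dynamic"),
            CombinationParams(1.0, 0.02, 0.0),
        )
        lo, hi = sorted((mu_s, mu_d))
        assert lo - 1e-12 <= out.mu <= hi + 1e-12
        assert out.sigma <= min(sg_s, sg_d) + 1e-12


class TestResponsesAndLikelihood:
    def test_vanishing_noise_reproduces_the_prediction(self, rng):
        bel = synthetic_beliefs(rng, 50)
        params = CombinationParams(1.0, 1e-12, 0.0)
        r = tb.simulate_responses(bel, params, rng)
        mu_sd = combined_mean("weighted", 1.0, 0.0, bel.mu_s, bel.sigma_s,
                              bel.mu_d, bel.sigma_d)
        np.testing.assert_allclose(r, mu_sd, atol=1e-10)

    def test_response_scatter_matches_k(self, rng):
        bel = synthetic_beliefs(rng, 10_000)
        params = CombinationParams(1.0, 0.03, 0.0)
        r = tb.simulate_responses(bel, params, rng)
        mu_sd = combined_mean("weighted", 1.0, 0.0, bel.mu_s, bel.sigma_s,
                              bel.mu_d, bel.sigma_d)
        assert np.std(r - mu_sd) == pytest.approx(0.03, rel=0.03)

    def test_responses_reproducible_under_seed(self, rng):
        bel = synthetic_beliefs(rng, 50)
        params = CombinationParams(1.0, 0.02, 0.0)
        r1 = tb.simulate_responses(bel, params, np.random.default_rng(4))
        r2 = tb.simulate_responses(bel, params, np.random.default_rng(4))
        np.testing.assert_array_equal(r1, r2)

    def test_single_trial_closed_form(self, rng):
        bel = synthetic_beliefs(rng, 1)
        params = CombinationParams(1.0, 1.0, 0.0)
        mu_sd = combined_mean("weighted", 1.0, 0.0, bel.mu_s, bel.sigma_s,
                              bel.mu_d, bel.sigma_d)
        logl = tb.log_likelihood(mu_sd, bel, params)
        assert logl == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-10)

    def test_matches_per_trial_density_product(self, rng):
        from scipy import stats

        bel = synthetic_beliefs(rng, 5)
        params = CombinationParams(1.2, 0.05, 0.01)
        r = tb.simulate_responses(bel, params, rng)
        mu_sd = combined_mean("weighted", 1.2, 0.01, bel.mu_s, bel.sigma_s,
                              bel.mu_d, bel.sigma_d)
        oracle = sum(
            stats.norm.logpdf(ri, mi, params.k) for ri, mi in zip(r, mu_sd)
        )
        assert tb.log_likelihood(r, bel, params) == pytest.approx(oracle, abs=1e-12)

    def test_likelihood_invariant_to_common_shift(self, rng):
        bel = synthetic_beliefs(rng, 100)
        params = CombinationParams(1.0, 0.03, 0.02)
        r = tb.simulate_responses(bel, params, rng)
        base = tb.log_likelihood(r, bel, params)
        c = 0.13
        shifted = BeliefArrays(bel.mu_s + c, bel.sigma_s, bel.mu_d + c, bel.sigma_d)
        moved = tb.log_likelihood(
            r + c, shifted, CombinationParams(1.0, 0.03, 0.02)
        )
        assert moved == pytest.approx(base, abs=1e-9)


class TestFitting:
    def test_parameter_recovery_on_long_series(self, rng):
        bel = synthetic_beliefs(rng, 2000)
        truth = CombinationParams(1.0, 0.02, 0.0)
        r = tb.simulate_responses(bel, truth, rng)
        fit = tb.fit_mle(r, bel, "weighted")
        assert fit.M == pytest.approx(1.0, abs=0.1)
        assert fit.k == pytest.approx(0.02, rel=0.1)
        assert fit.b == pytest.approx(0.0, abs=0.005)
        assert fit.bic == pytest.approx(3 * np.log(2000) - 2 * fit.log_lik)

    def test_pure_statistical_responder_drives_m_up(self, rng):
        bel = synthetic_beliefs(rng, 400)
        r = bel.mu_s + rng.normal(0, 0.005, 400)
        fit = tb.fit_mle(r, bel, "weighted")
        assert fit.M > 1.5

    def test_one_dimensional_profile_matches_dense_grid(self, rng):
        bel = synthetic_beliefs(rng, 500)
        truth = CombinationParams(1.3, 0.02, 0.0)
        r = tb.simulate_responses(bel, truth, rng)
        fit = tb.fit_mle(r, bel, "weighted", free_params=("M",))
        dense = np.linspace(0, 2, 2001)
        logls = [
            tb.log_likelihood(r, bel, CombinationParams(m, fit.k, 0.0))
            for m in dense
        ]
        assert fit.M == pytest.approx(dense[np.argmax(logls)], abs=0.01)

    def test_nested_version_has_fewer_parameters_in_bic(self, rng):
        bel = synthetic_beliefs(rng, 300)
        r = tb.simulate_responses(bel, CombinationParams(1.0, 0.02, 0.0), rng)
        full = tb.fit_mle(r, bel, "weighted")
        nested = tb.fit_mle(r, bel, "weighted", free_params=("k",))
        assert len(nested.free_params) == 1
        assert full.log_lik >= nested.log_lik - 1e-6

    def test_too_few_trials_rejected(self, rng):
        bel = synthetic_beliefs(rng, 10)
        with pytest.raises(ConfigurationError):
            tb.fit_mle(np.zeros(10), bel, "weighted")


class TestComparison:
    def test_identical_fits_have_zero_loglr_and_antisymmetry(self, rng):
        bel = synthetic_beliefs(rng, 200)
        r = tb.simulate_responses(bel, CombinationParams(1.0, 0.02, 0.0), rng)
        fw = tb.fit_mle(r, bel, "weighted")
        fs = tb.fit_mle(r, bel, "select")
        table = tb.compare_models([fw, fw])
        assert table["loglr"].iloc[0] == 0.0
        ab = tb.compare_models([fw, fs])["loglr"].iloc[0]
        ba = tb.compare_models([fs, fw])["loglr"].iloc[0]
        assert ab == pytest.approx(-ba)

    def test_mismatched_trial_sets_rejected(self, rng):
        bel_a, bel_b = synthetic_beliefs(rng, 200), synthetic_beliefs(rng, 100)
        ra = tb.simulate_responses(bel_a, CombinationParams(1.0, 0.02, 0.0), rng)
        rb = tb.simulate_responses(bel_b, CombinationParams(1.0, 0.02, 0.0), rng)
        fa = tb.fit_mle(ra, bel_a, "weighted")
        fb = tb.fit_mle(rb, bel_b, "weighted")
        with pytest.raises(ConfigurationError):
            tb.compare_models([fa, fb])

    def test_generating_model_wins_likelihood_in_most_replicates(self, rng):
        """Model recovery at small scale: for each generator the generating
        model attains the highest logL in the majority of replicates."""
        wins = {kind: 0 for kind in ("weighted", "unweighted", "select")}
        n_rep = 12
        for kind in wins:
            for rep in range(n_rep):
                local = np.random.default_rng(1000 + rep)
                bel = synthetic_beliefs(local, 200)
                truth = CombinationParams(
                    0.5 if kind == "unweighted" else 1.0, 0.02, 0.0, kind
                )
                r = tb.simulate_responses(bel, truth, local)
                logls = {
                    k: tb.fit_mle(r, bel, k).log_lik
                    for k in ("weighted", "unweighted", "select")
                }
                wins[kind] += max(logls, key=logls.get) == kind
        for kind, n_won in wins.items():
            assert n_won > n_rep / 2, (kind, wins)


class TestAttractionSlopes:
    def test_limiting_responders_bracket_the_slope(self, default_session,
                                                   session_beliefs):
        x = default_session.endpoints[default_session.analysis_mask]
        stat_only = tb.attraction_slope_analysis(
            default_session, session_beliefs.mu_s, session_beliefs
        )
        dyn_only = tb.attraction_slope_analysis(
            default_session, x, session_beliefs
        )
        np.testing.assert_allclose(stat_only["slope"], 1.0, atol=1e-9)
        np.testing.assert_allclose(dyn_only["slope"], 0.0, atol=1e-9)

    def test_optimal_reference_slope_matches_analytic_weight(
        self, default_session, session_beliefs
    ):
        table = tb.attraction_slope_analysis(
            default_session,
            default_session.endpoints[default_session.analysis_mask],
            session_beliefs,
        )
        bel = session_beliefs
        edges = np.quantile(bel.sigma_d, np.linspace(0, 1, 4))
        edges[-1] = np.inf
        x = default_session.endpoints[default_session.analysis_mask]
        for b in range(3):
            in_bin = (bel.sigma_d >= edges[b]) & (bel.sigma_d < edges[b + 1])
            w = bel.sigma_d[in_bin] ** 2 / (
                bel.sigma_d[in_bin] ** 2 + bel.sigma_s[in_bin] ** 2
            )
            # regression slope weights each trial by its squared displacement
            # from the statistical mean
            d2 = (x[in_bin] - bel.mu_s[in_bin]) ** 2
            oracle = float((w * d2).sum() / d2.sum())
            assert table["slope_optimal"].iloc[b] == pytest.approx(
                oracle, abs=0.1
            )

    def test_slopes_rise_with_trajectory_noise_for_optimal_observers(
        self, default_session, session_beliefs, rng
    ):
        r_opt = combined_mean(
            "weighted", 1.0, 0.0,
            session_beliefs.mu_s, session_beliefs.sigma_s,
            session_beliefs.mu_d, session_beliefs.sigma_d,
        ) + rng.normal(0, 0.01, len(session_beliefs))
        table = tb.attraction_slope_analysis(
            default_session, r_opt, session_beliefs
        )
        slopes = table["slope"].to_numpy()
        assert slopes[0] < slopes[1] < slopes[2]
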