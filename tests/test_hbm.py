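"""Hierarchical model graph, MCMC machinery, diagnostics and DIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cppddm.hbm import (
    MODEL_TABLE,
    ModelSpec,
    PosteriorSamples,
    SamplerSettings,
    build_model,
    compute_dic,
    gelman_rubin,
    posterior_predictive,
    sample_posterior,
    sum_to_zero_design,
    total_deviance,
)
from cppddm.hbm.sampler import _Chain
from cppddm.simulate import SimConfig, gen_behavior


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(
        n_participants=8, n_trials_per_condition=24,
        covariate_effects={("delta", "age"): 0.45}, seed=11,
    )
    return gen_behavior(cfg)


@pytest.fixture(scope="module")
def fitted(cohort):
    trials, truth = cohort
    graph = build_model(MODEL_TABLE["model1"], trials)
    settings = SamplerSettings(n_chains=3, n_samples=700, n_burnin=300, thin=1, seed=5)
    return sample_posterior(graph, settings)


class TestSumToZeroDesign:
    @pytest.mark.parametrize("k", [2, 3, 4, 7])
    def test_orthonormal_zero_sum_columns(self, k):
        q = sum_to_zero_design(k)
        assert q.shape == (k, k - 1)
        np.testing.assert_allclose(q.T @ q, np.eye(k - 1), atol=1e-12)
        np.testing.assert_allclose(q.sum(axis=0), 0.0, atol=1e-12)

    def test_zero_effects_zero_offsets(self):
        q = sum_to_zero_design(3)
        np.testing.assert_allclose(q @ np.zeros(2), 0.0)

    def test_any_effects_sum_to_zero(self):
        q = sum_to_zero_design(3)
        rng = np.random.default_rng(0)
        for _ in range(20):
            offs = q @ rng.normal(size=2)
            assert offs.sum() == pytest.approx(0.0, abs=1e-12)

    def test_k_below_two_raises(self):
        with pytest.raises(ValueError):
            sum_to_zero_design(1)


class TestBuildModel:
    def test_node_bookkeeping_model1(self, cohort):
        """Model 1 parameter count: 3P + kP + 8 group nodes + (k-1) effects
        + 1 g scale."""
        trials, _ = cohort
        g = build_model(MODEL_TABLE["model1"], trials)
        P, k = g.n_participants, g.n_conditions
        assert g.n_parameters() == 3 * P + k * P + 8 + (k - 1) + 1
        names = g.node_names()
        assert "mu_delta" in names and "theta[1]" in names
        assert not any(n.startswith("b_") for n in names)

    def test_covariate_models_add_weight_nodes(self, cohort):
        trials, truth = cohort
        cov = truth.rename(columns={"z_age": "age"})[["participant_id", "age"]]
        g = build_model(MODEL_TABLE["model4"], trials, cov)
        assert "b_delta_age" in g.node_names()
        assert "b_alpha_age" in g.node_names()

    def test_missing_covariates_error_lists_ids(self, cohort):
        trials, truth = cohort
        cov = truth.rename(columns={"z_age": "age"})[["participant_id", "age"]].iloc[:-2]
        with pytest.raises(ValueError, match="missing for participants"):
            build_model(MODEL_TABLE["model3"], trials, cov)

    def test_prior_predictive_respects_bounds(self, cohort):
        trials, _ = cohort
        g = build_model(MODEL_TABLE["model1"], trials)
        draws = g.prior_predictive(np.random.default_rng(0), n_draws=50)
        for par in ("alpha", "beta", "tau"):
            lo, hi = g.bounds[par]
            assert np.all((draws[par] >= lo) & (draws[par] <= hi))
        lo, hi = g.bounds["delta"]
        assert np.all((draws["delta"] >= lo) & (draws["delta"] <= hi))

    def test_prior_predictive_age_slope(self, cohort):
        """With the age weight clamped at 0.45, the prior-predictive mean
        drift regresses on z(age) with slope ~ 0.45 * sigma_eps."""
        trials, truth = cohort
        cov = truth.rename(columns={"z_age": "age"})[["participant_id", "age"]]
        g = build_model(MODEL_TABLE["model3"], trials, cov)
        fixed = {
            "b_delta_age": 0.45, "mu_delta": 2.0, "sigma_eps": 0.6,
            "theta[0]": 0.0, "theta[1]": 0.0,
        }
        draws = g.prior_predictive(np.random.default_rng(1), n_draws=4000, fixed=fixed)
        z = g.Z["delta"]["age"]
        dbar = draws["delta"].mean(axis=(0, 2))  # mean over draws and conditions
        slope = np.polyfit(z, dbar, 1)[0]
        assert slope == pytest.approx(0.45 * 0.6, abs=0.03)

    def test_unsupported_covariate_parameter_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", {"beta": ["age"]})


class TestSampler:
    def test_seed_determinism(self, cohort):
        trials, _ = cohort
        graph = build_model(MODEL_TABLE["model1"], trials)
        settings = SamplerSettings(n_chains=2, n_samples=120, n_burnin=60, thin=2, seed=3)
        a = sample_posterior(graph, settings)
        b = sample_posterior(graph, settings)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])
        np.testing.assert_array_equal(a.deviance, b.deviance)
        assert a.deviance.shape == (2, 30)

    def test_draws_respect_truncation_bounds(self, fitted):
        g = fitted.graph
        for par in ("alpha", "beta", "tau", "delta"):
            lo, hi = g.bounds[par]
            x = fitted.stacked(par)
            assert x.min() >= lo and x.max() <= hi

    def test_starting_point_near_half_on_balanced_data(self, fitted):
        """Direction-balanced data give starting points near 0.5."""
        assert fitted.stacked("mu_beta").mean() == pytest.approx(0.5, abs=0.05)

    def test_group_mean_conditional_matches_conjugate_oracle(self, cohort):
        """With the participant-level parameters clamped, the group-mean
        update targets the conjugate normal posterior (truncation bounds
        far away), so its sample mean/SD must match the closed form."""
        trials, _ = cohort
        graph = build_model(MODEL_TABLE["model1"], trials)
        rng = np.random.default_rng(7)
        chain = _Chain(graph, rng)
        # clamp everything except mu_alpha (including the interweaved
        # scale moves, which would free sigma and the participant block)
        data = rng.normal(1.2, 0.2, graph.n_participants)
        chain.alpha = data
        chain.state["sigma_alpha"] = 0.2
        chain.hyper_sc = {"mu_alpha": 0.1}
        chain.rescale_move = lambda *a, **k: None
        for key in chain.sc:
            chain.sc[key][...] = 0.0
        out = []
        for i in range(4000):
            chain.sweep()
            if i >= 500:
                out.append(chain.state["mu_alpha"])
        m0, s0 = 1.0, 0.5  # prior on the boundary-separation group mean
        prec = 1 / s0**2 + len(data) / 0.2**2
        post_mean = (m0 / s0**2 + data.sum() / 0.2**2) / prec
        post_sd = np.sqrt(1 / prec)
        out = np.asarray(out)
        n_eff = len(out) / (1 + 20)  # generous autocorrelation allowance
        assert out.mean() == pytest.approx(post_mean, abs=4 * post_sd / np.sqrt(n_eff))
        assert out.std() == pytest.approx(post_sd, rel=0.25)


class TestGelmanRubin:
    @staticmethod
    def _samples(chains):
        draws = {"x": np.asarray(chains)}
        return PosteriorSamples(draws=draws, deviance=np.zeros_like(chains))

    def test_copied_chains_give_one(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=500)
        rh = gelman_rubin(self._samples(np.stack([c, c, c])))
        assert rh["x"] <= 1 + 1e-12

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(self._samples(chains))["x"] > 1.1

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(2)
        ok = 0
        for _ in range(100):
            chains = rng.normal(size=(3, 1000))
            r = gelman_rubin(self._samples(chains))["x"]
            ok += 0.99 <= r <= 1.02
        assert ok >= 95

    def test_single_chain_raises(self):
        with pytest.raises(ValueError):
            gelman_rubin(self._samples(np.zeros((1, 100))))

    def test_fitted_model_converges(self, fitted):
        rh = gelman_rubin(fitted)
        scalars = [n for n in rh.index if n.split("[")[0] in
                   ("mu_alpha", "mu_beta", "mu_tau", "mu_delta", "sigma_eps", "theta")]
        assert rh[scalars].max() < 1.1


class TestDIC:
    def test_point_mass_posterior_zero_complexity(self, fitted):
        g = fitted.graph
        point = {
            "alpha": fitted.stacked("alpha").mean(axis=0),
            "beta": fitted.stacked("beta").mean(axis=0),
            "tau": fitted.stacked("tau").mean(axis=0),
            "delta": fitted.stacked("delta").mean(axis=0),
        }
        d = total_deviance(g, point["alpha"], point["beta"], point["tau"], point["delta"])
        draws = {k: np.broadcast_to(v, (2, 10) + v.shape).copy() for k, v in point.items()}
        degenerate = PosteriorSamples(
            draws=draws, deviance=np.full((2, 10), d), metadata={}, graph=g
        )
        dic, p_d, mean_dev = compute_dic(degenerate)
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert dic == pytest.approx(d, rel=1e-12)

    def test_posterior_spread_gives_positive_complexity(self, fitted):
        dic, p_d, mean_dev = compute_dic(fitted)
        assert p_d > 0
        assert dic == pytest.approx(mean_dev + p_d)

    def test_missing_deviance_trace_errors(self, fitted):
        broken = PosteriorSamples(draws=fitted.draws, deviance=np.array([]), graph=fitted.graph)
        with pytest.raises(ValueError):
            compute_dic(broken)


class TestPosteriorPredictive:
    def test_calibration_and_monotonicity(self, fitted, cohort):
        """Data simulated from the model: observed accuracy and RT
        quantiles fall inside the central 95% predictive band for most
        cells, and predictive accuracy rises with coherence."""
        trials, _ = cohort
        reps, obs = posterior_predictive(fitted, trials, n_rep=40, seed=1)
        merged_cols = ["participant_id", "coherence_pct"]
        inside = []
        for col in ("accuracy", "q10", "q50", "q90"):
            lo = reps.groupby(merged_cols)[col].quantile(0.025)
            hi = reps.groupby(merged_cols)[col].quantile(0.975)
            o = obs.set_index(merged_cols)[col]
            inside.append(((o >= lo) & (o <= hi)).mean())
        assert np.mean(inside) >= 0.9

        # predictive accuracy follows the fitted drift ordering cell by
        # cell (absorption probability is monotone in drift)
        g = fitted.graph
        dbar = fitted.stacked("delta").mean(axis=0)  # P x k posterior means
        acc = reps.groupby(merged_cols)["accuracy"].mean()
        cells = pd.DataFrame(
            {
                "delta": dbar.ravel(),
                "acc": [
                    acc.loc[(pid, coh)]
                    for pid in g.participants
                    for coh in g.conditions
                ],
            }
        )
        assert cells["delta"].corr(cells["acc"], method="spearman") > 0.8
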