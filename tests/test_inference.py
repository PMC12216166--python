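"""Hierarchical fitting: joint density, gradients, both algorithms."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import volabandit as vb
from volabandit import _likelihoods as lk
from volabandit.errors import ValidationError
from volabandit.inference import hyper_log_prior

from test_models import hand_trace_m11, hand_trace_trials


@pytest.fixture(scope="module")
def tiny_dataset(m11):
    hyper = vb.default_group_hyper(m11)
    cohort = vb.sample_cohort(hyper, 6, m11, seed=21)
    trials = vb.simulate_cohort(cohort, vb.TaskConfig(), seed=21)
    return cohort, trials


class TestJointLogDensity:
    def test_single_participant_decomposition(self, m11, tiny_dataset):
        cohort, trials = tiny_dataset
        one = trials[trials.participant_id == "P001"]
        z = lk.unconstrain(cohort.theta()[[0]], m11.parameter_names)
        mu = np.zeros(5)
        sigma = np.full(5, 2.0)
        joint = vb.joint_log_density(m11, {"mu": mu, "sigma": sigma}, z, one)
        ll, _ = vb.session_loglik(m11, cohort.params[0], one)
        normal_term = float(np.sum(-0.5 * ((z[0] - mu) / sigma) ** 2
                                   - np.log(sigma) - 0.5 * math.log(2 * math.pi)))
        assert joint == pytest.approx(hyper_log_prior(mu, sigma) + ll + normal_term,
                                      abs=1e-9)

    def test_density_difference_is_prior_only_for_identical_likelihoods(
            self, m11, tiny_dataset):
        """Two hyper-draws, same participant draws: the likelihood cancels."""
        cohort, trials = tiny_dataset
        z = lk.unconstrain(cohort.theta(), m11.parameter_names)
        h1 = {"mu": np.zeros(5), "sigma": np.ones(5)}
        h2 = {"mu": np.full(5, 0.3), "sigma": np.full(5, 1.5)}
        d = (vb.joint_log_density(m11, h2, z, trials)
             - vb.joint_log_density(m11, h1, z, trials))
        prior = lambda h: (hyper_log_prior(h["mu"], h["sigma"])
                           + float(np.sum(-0.5 * ((z - h["mu"]) / h["sigma"]) ** 2
                                          - np.log(h["sigma"])
                                          - 0.5 * math.log(2 * math.pi))))
        assert d == pytest.approx(prior(h2) - prior(h1), abs=1e-9)

    def test_dimension_mismatch_rejected(self, m11, tiny_dataset):
        _, trials = tiny_dataset
        with pytest.raises(ValidationError):
            vb.joint_log_density(m11, {"mu": np.zeros(4), "sigma": np.ones(4)},
                                 np.zeros((6, 5)), trials)

    def test_analytic_gradient_matches_finite_differences(self, m11, tiny_dataset):
        _, trials = tiny_dataset
        model = vb.HierarchicalBanditModel(trials, m11)
        rng = np.random.default_rng(0)
        for _ in range(10):
            theta = rng.normal(0.0, 0.4, model.dim)
            g = model.score(theta)
            idx = rng.choice(model.dim, 6, replace=False)
            eps = 1e-6
            for j in idx:
                e = np.zeros(model.dim)
                e[j] = eps
                fd = (model.loglike(theta + e) - model.loglike(theta - e)) / (2 * eps)
                assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestFit:
    def test_null_model_pointwise_is_log_half(self, tiny_dataset):
        _, trials = tiny_dataset
        res = vb.fit(vb.get_spec("M0"), trials,
                     vb.FitSettings(algorithm="map_laplace", n_chains=2, n_samples=50))
        pw = res.pointwise_loglik()
        assert pw.shape == (100, 6, 160)
        np.testing.assert_allclose(pw, math.log(0.5))

    def test_pointwise_sums_match_session_totals(self, m11, m11_fit_small, small_cohort):
        _, trials = small_cohort
        pw = m11_fit_small.pointwise_loglik()
        sd = lk.pack_sessions(trials)
        s = 7  # arbitrary draw
        ll, _ = lk.loglik_grad(vb.get_spec("M11"), sd, m11_fit_small.draws.theta[s])
        np.testing.assert_allclose(pw[s].sum(axis=1), ll, atol=1e-9)

    def test_hand_trace_pointwise_at_fixed_draw(self, m11):
        trials = vb.trials_to_frame(hand_trace_trials())
        theta = np.array([[0.5, 0.2, 0.4, 0.6, 0.8]])
        sd = lk.pack_sessions(trials)
        pw = lk.pointwise(m11, sd, theta)
        np.testing.assert_allclose(pw[0], hand_trace_m11(), atol=1e-12)

    def test_deterministic_given_seed(self, m11, tiny_dataset):
        _, trials = tiny_dataset
        st = vb.FitSettings(algorithm="map_laplace", n_chains=2, n_samples=50, seed=12)
        a = vb.fit(m11, trials, st)
        b = vb.fit(m11, trials, st)
        np.testing.assert_array_equal(a.draws.theta, b.draws.theta)

    def test_shrinkage_increases_as_sigma_prior_tightens(self, m11, tiny_dataset):
        """Participant spread shrinks monotonically with the sigma prior."""
        _, trials = tiny_dataset
        spreads = []
        for scale in (2.0, 0.5, 0.1):
            res = vb.fit(m11, trials,
                         vb.FitSettings(algorithm="map_laplace", n_chains=2,
                                        n_samples=100, seed=0),
                         priors=vb.PriorConfig(sigma_scale=scale))
            est = res.draws.participant_posterior_mean()["alpha_neg_stable"]
            spreads.append(float(est.var()))
        assert spreads[0] >= spreads[1] >= spreads[2]

    def test_summary_and_diagnostics_present(self, m11_fit_small):
        s = m11_fit_small.summary()
        assert list(s["parameter"]) == list(vb.get_spec("M11").parameter_names)
        assert np.isfinite(s["group_mean"]).all()
        diag = m11_fit_small.diagnostics
        # every sampled quantity carries R-hat and ESS
        assert len(diag) == 5 * 2 + 10 * 5
        assert np.isfinite(diag["rhat"]).all()

    def test_posterior_draw_container_round_trip(self, m11_fit_small, tmp_path):
        path = tmp_path / "posterior.nc"
        m11_fit_small.draws.to_netcdf(path, diagnostics_sidecar=str(tmp_path / "d.json"))
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        assert ds.attrs["model_id"] == "M11"
        assert ds["theta"].dims == ("chain", "draw", "participant", "parameter")
        np.testing.assert_allclose(
            ds["theta"].values.reshape(m11_fit_small.draws.theta.shape),
            m11_fit_small.draws.theta)

    def test_insufficient_data_rejected(self, m11):
        df = vb.trials_to_frame(hand_trace_trials()[:1])
        with pytest.raises(ValidationError):
            vb.HierarchicalBanditModel(df, m11)


class TestAlgorithmAgreement:
    def test_map_laplace_and_mcmc_group_means_agree(self):
        """Point estimates of the two algorithms coincide on an easy problem."""
        m4 = vb.get_spec("M4")
        hyper = vb.default_group_hyper(m4)
        cohort = vb.sample_cohort(hyper, 15, m4, seed=8)
        trials = vb.simulate_cohort(cohort, vb.TaskConfig(), seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lap = vb.fit(m4, trials, vb.FitSettings(algorithm="map_laplace",
                                                    n_chains=2, n_samples=400, seed=0))
            mc = vb.fit(m4, trials, vb.FitSettings(algorithm="mcmc", n_chains=2,
                                                   n_warmup=800, n_samples=800, seed=0))
        g_lap = lap.draws.group_mean_constrained().set_index("parameter")["mean"]
        g_mc = mc.draws.group_mean_constrained().set_index("parameter")["mean"]
        assert (g_lap - g_mc).abs().max() < 0.05

    def test_prior_predictive_covers_parameter_ranges(self, m11):
        """Constrained prior draws span (0,1) for alphas and a broad tau range
        without piling at the boundaries."""
        rng = np.random.default_rng(0)
        pr = vb.PriorConfig()
        mu = rng.normal(pr.mu_loc, pr.mu_scale, size=(4000, 5))
        sigma = np.abs(rng.normal(0, pr.sigma_scale, size=(4000, 5)))
        z = mu + sigma * rng.standard_normal((4000, 5))
        theta = lk.constrain(z, vb.get_spec("M11").parameter_names)
        alphas = theta[:, 1:]
        assert alphas.min() < 0.05 and alphas.max() > 0.95
        assert 0.2 < ((alphas > 0.25) & (alphas < 0.75)).mean() < 0.8
        tau = theta[:, 0]
        assert np.quantile(tau, 0.05) < 0.1 and np.quantile(tau, 0.95) > 2.0
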