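"""Likelihood, priors, conjugate updates, sampler behaviour, diagnostics, DIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from aircco import model
from aircco.model import (
    ModelData,
    ModelSpec,
    ParameterState,
    Posterior,
    dic,
    diagnostics,
    fit_mcmc,
    log_likelihood,
    log_posterior,
    log_prior,
    tau_beta_full_conditional,
    tau_d_full_conditional,
)


def _state(alpha=0.0, betas=(0.0,), d=(), tau_beta=None, tau_d=1.0, sd_alpha=1.0):
    betas = np.asarray(betas, dtype=float)
    if tau_beta is None:
        tau_beta = np.ones_like(betas)
    return ParameterState(
        alpha=alpha, betas=betas, d=np.asarray(d, dtype=float),
        tau_beta=np.asarray(tau_beta, dtype=float), tau_d=tau_d, sd_alpha=sd_alpha,
    )


def _toy_data(n=6, p=2, strata=True, seed=0):
    rng = np.random.default_rng(seed)
    rows = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    rows["y"] = rng.integers(0, 2, size=n)
    rows["stratum"] = rng.integers(1, 3, size=n)
    spec = ModelSpec(
        covariates=tuple(f"x{j}" for j in range(p)), include_strata=strata
    )
    return ModelData.from_rows(rows, spec), spec


class TestLogLikelihood:
    def test_all_parameters_zero_gives_n_log_half(self):
        data, _ = _toy_data(n=10)
        state = _state(betas=np.zeros(2), d=np.zeros(data.n_strata))
        assert log_likelihood(state, data) == pytest.approx(10 * np.log(0.5))

    def test_matches_hand_summed_bernoulli_on_toy_table(self):
        data, _ = _toy_data(n=6, seed=3)
        rng = np.random.default_rng(4)
        state = _state(
            alpha=rng.normal(), betas=rng.normal(size=2),
            d=rng.normal(size=data.n_strata),
        )
        expected = 0.0
        for i in range(6):
            eta = state.alpha + data.X[i] @ state.betas + state.d[data.stratum_codes[i]]
            pi = expit(eta)
            expected += data.y[i] * np.log(pi) + (1 - data.y[i]) * np.log(1 - pi)
        got = log_likelihood(state, data)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_saturates_to_zero_for_all_ones(self):
        rows = pd.DataFrame({"x0": np.zeros(5), "y": np.ones(5), "stratum": 1})
        data = ModelData.from_rows(rows, ModelSpec(("x0",), include_strata=False))
        lls = [
            log_likelihood(_state(alpha=a, betas=[0.0]), data) for a in (2, 5, 10, 20)
        ]
        assert all(np.diff(lls) > 0) and lls[-1] > -1e-4

    def test_dimension_mismatch_rejected(self):
        data, _ = _toy_data()
        with pytest.raises(ValueError, match="dimension"):
            log_likelihood(_state(betas=np.zeros(5)), data)

    def test_covariate_shift_absorbed_by_intercept(self):
        """Centring consistency: x -> x + c with alpha -> alpha - beta*c."""
        data, _ = _toy_data(n=30, seed=6)
        state = _state(alpha=0.3, betas=[0.5, -0.2], d=np.zeros(data.n_strata))
        shifted = ModelData(
            data.y, data.X + np.array([2.0, -1.0]), data.covariates,
            data.stratum_codes, data.stratum_labels,
        )
        state2 = _state(
            alpha=0.3 - 0.5 * 2.0 - (-0.2) * (-1.0), betas=[0.5, -0.2],
            d=np.zeros(data.n_strata),
        )
        assert log_likelihood(state, data) == pytest.approx(
            log_likelihood(state2, shifted), rel=1e-12
        )


class TestLogPrior:
    def test_sd_alpha_outside_uniform_support(self):
        spec = ModelSpec(("x0",))
        assert log_prior(_state(sd_alpha=5.0), spec) == -np.inf
        assert log_prior(_state(sd_alpha=-0.1), spec) == -np.inf
        assert np.isfinite(log_prior(_state(sd_alpha=3.9), spec))

    def test_tau_d_gamma_density_closed_form(self):
        # Gamma(shape 2, rate 0.5) at tau = 1: log(0.25 * 1 * e^-0.5)
        spec = ModelSpec(("x0",))
        base = log_prior(_state(tau_d=1.0), spec)
        other = log_prior(_state(tau_d=2.0), spec)
        expected_delta = (np.log(0.25) - 0.5) - (np.log(0.25 * 2) - 1.0)
        assert base - other == pytest.approx(expected_delta, rel=1e-12)

    def test_each_zero_stratum_effect_adds_standard_normal_density(self):
        spec = ModelSpec(("x0",))
        lp1 = log_prior(_state(d=np.zeros(3), tau_d=1.0), spec)
        lp2 = log_prior(_state(d=np.zeros(6), tau_d=1.0), spec)
        assert lp2 - lp1 == pytest.approx(3 * np.log(1 / np.sqrt(2 * np.pi)))

    def test_log_posterior_is_sum_of_parts(self):
        data, spec = _toy_data(n=12, seed=7)
        rng = np.random.default_rng(8)
        for _ in range(5):
            state = _state(
                alpha=rng.normal(), betas=rng.normal(size=2),
                d=rng.normal(size=data.n_strata),
                tau_beta=rng.gamma(2, 1, size=2), tau_d=rng.gamma(2, 2),
                sd_alpha=rng.uniform(0.1, 3.9),
            )
            assert log_posterior(state, data, spec) == pytest.approx(
                log_prior(state, spec) + log_likelihood(state, data), rel=1e-12
            )


class TestConjugateUpdates:
    def test_tau_d_full_conditional_parameters(self):
        d = np.array([0.3, -0.2, 0.5, 0.1])
        shape, rate = tau_d_full_conditional(d)
        assert shape == pytest.approx(2 + len(d) / 2)
        assert rate == pytest.approx(0.5 + 0.5 * float(d @ d))

    def test_tau_d_gibbs_moments_match_closed_form(self):
        rng = np.random.default_rng(11)
        d = rng.normal(0, 0.5, size=40)
        shape, rate = tau_d_full_conditional(d)
        draws = rng.gamma(shape, 1.0 / rate, size=200_000)
        assert draws.mean() == pytest.approx(shape / rate, rel=0.01)
        assert draws.var() == pytest.approx(shape / rate**2, rel=0.02)

    def test_tau_beta_full_conditional_parameters(self):
        shape, rate = tau_beta_full_conditional(0.4)
        assert (shape, rate) == (pytest.approx(2.5), pytest.approx(1.08))


class TestSampler:
    def test_reproducible_under_seed(self):
        data, spec = _toy_data(n=40, seed=12)
        rows = pd.DataFrame(data.X, columns=data.covariates)
        rows["y"], rows["stratum"] = data.y, data.stratum_codes
        a = fit_mcmc(rows, spec, n_iter=300, n_burnin=100, n_chains=2, seed=5)
        b = fit_mcmc(rows, spec, n_iter=300, n_burnin=100, n_chains=2, seed=5)
        c = fit_mcmc(rows, spec, n_iter=300, n_burnin=100, n_chains=2, seed=6)
        assert np.array_equal(a.draws["beta"], b.draws["beta"])
        assert not np.array_equal(a.draws["beta"], c.draws["beta"])

    def test_zero_information_covariate_samples_its_prior(self):
        """A constant (all-zero once centred) covariate's posterior equals its
        marginal prior: beta | tau ~ N(0, 1/tau), tau ~ Gamma(2, 1), i.e. a
        scaled Student-t with 4 df."""
        rng = np.random.default_rng(13)
        rows = pd.DataFrame(
            {
                "flat": np.zeros(120),
                "y": rng.integers(0, 2, size=120).astype(float),
                "stratum": 1,
            }
        )
        spec = ModelSpec(("flat",), include_strata=False)
        post = fit_mcmc(rows, spec, n_iter=9000, n_burnin=1500, n_chains=2, seed=3)
        draws = post.beta("flat")
        marginal = stats.t(df=4, scale=np.sqrt(0.5))
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert np.quantile(draws, q) == pytest.approx(
                marginal.ppf(q), abs=0.12
            )

    def test_agrees_with_conditional_logistic_oracle(self):
        """Dual-route check on a calibration-config study: posterior medians
        track the classical conditional-logit estimates on the same rows."""
        from aircco import design, synthetic_data, validation

        cfg = validation.calibration_config(21, true_betas=validation.TRUE_BETAS)
        exposures = synthetic_data.generate_exposures(cfg)
        visits = synthetic_data.generate_visits(exposures, cfg)
        rng = np.random.default_rng(21)
        rows, _ = design.build_rows(
            visits, exposures, rng, covariates=["NOx", "temperature"]
        )
        cl = model.fit_conditional_logistic(rows, ["NOx", "temperature"])
        centred, _ = design.center_covariates(rows, ["NOx", "temperature"])
        spec = ModelSpec(("NOx", "temperature"))
        post = fit_mcmc(centred, spec, n_iter=2200, n_burnin=800, n_chains=2, seed=21)
        assert np.median(post.beta("NOx")) == pytest.approx(cl["NOx"], abs=0.008)
        assert np.median(post.beta("temperature")) == pytest.approx(
            cl["temperature"], abs=0.008
        )


def _fake_posterior(draw_fn, n_chains=2, n_draws=1000, seed=0):
    rng = np.random.default_rng(seed)
    alpha = draw_fn(rng, (n_chains, n_draws))
    draws = {
        "alpha": alpha,
        "beta": draw_fn(rng, (n_chains, n_draws, 1)),
        "tau_beta": np.abs(draw_fn(rng, (n_chains, n_draws, 1))) + 0.5,
        "tau_d": np.abs(draw_fn(rng, (n_chains, n_draws))) + 0.5,
        "sd_alpha": np.abs(draw_fn(rng, (n_chains, n_draws))) * 0.1 + 1.0,
    }
    return Posterior(
        draws=draws, loglik=np.zeros((n_chains, n_draws)), covariates=("x0",),
        stratum_labels=None, spec=ModelSpec(("x0",), include_strata=False),
        n_chains=n_chains, n_iter=n_draws, n_burnin=0, thin=1, seed=seed,
    )


class TestDiagnostics:
    def test_iid_chains_have_rhat_near_one_and_full_ess(self):
        post = _fake_posterior(lambda rng, s: rng.standard_normal(s))
        report = diagnostics(post).set_index("parameter")
        assert 1.0 <= report.loc["alpha", "rhat"] <= 1.02
        assert abs(report.loc["alpha", "ess"] - 2000) < 0.2 * 2000
        assert not report["flagged"].any()

    def test_non_mixing_chains_flagged(self):
        post = _fake_posterior(lambda rng, s: rng.standard_normal(s) * 0.01)
        post.draws["alpha"] = post.draws["alpha"] + np.array([[0.0], [5.0]])
        report = diagnostics(post).set_index("parameter")
        assert report.loc["alpha", "rhat"] > 1.05
        assert report.loc["alpha", "flagged"]

    def test_single_chain_warns_and_omits_rhat(self):
        post = _fake_posterior(lambda rng, s: rng.standard_normal(s), n_chains=1)
        with pytest.warns(UserWarning, match="2 chains"):
            report = diagnostics(post)
        assert report["rhat"].isna().all()


class TestDic:
    def _posterior_from_states(self, data, states):
        draws = {
            "alpha": np.array([[s.alpha for s in states]]),
            "beta": np.array([[s.betas for s in states]]),
            "tau_beta": np.array([[s.tau_beta for s in states]]),
            "tau_d": np.array([[s.tau_d for s in states]]),
            "sd_alpha": np.array([[s.sd_alpha for s in states]]),
            "d": np.array([[s.d for s in states]]),
        }
        loglik = np.array([[log_likelihood(s, data) for s in states]])
        return Posterior(
            draws=draws, loglik=loglik, covariates=data.covariates,
            stratum_labels=data.stratum_labels,
            spec=ModelSpec(data.covariates), n_chains=1,
            n_iter=len(states), n_burnin=0, thin=1, seed=0,
        )

    def test_degenerate_posterior_has_zero_effective_parameters(self):
        data, _ = _toy_data(n=20, seed=14)
        state = _state(alpha=0.4, betas=[0.2, -0.1], d=np.zeros(data.n_strata))
        post = self._posterior_from_states(data, [state] * 50)
        result = dic(post, data)
        assert result.p_d == pytest.approx(0.0, abs=1e-9)
        assert result.dic == pytest.approx(-2 * log_likelihood(state, data))

    def test_matches_direct_two_pass_computation(self):
        data, _ = _toy_data(n=20, seed=15)
        rng = np.random.default_rng(16)
        states = [
            _state(
                alpha=rng.normal(), betas=rng.normal(size=2),
                d=rng.normal(size=data.n_strata) * 0.1,
            )
            for _ in range(40)
        ]
        post = self._posterior_from_states(data, states)
        result = dic(post, data)
        devs = np.array([-2 * log_likelihood(s, data) for s in states])
        mean_state = ParameterState(
            alpha=np.mean([s.alpha for s in states]),
            betas=np.mean([s.betas for s in states], axis=0),
            d=np.mean([s.d for s in states], axis=0),
            tau_beta=np.ones(2), tau_d=1.0, sd_alpha=1.0,
        )
        d_hat = -2 * log_likelihood(mean_state, data)
        assert result.mean_deviance == pytest.approx(devs.mean(), rel=1e-12)
        assert result.dic == pytest.approx(2 * devs.mean() - d_hat, rel=1e-12)

    def test_noise_covariate_usually_raises_dic(self):
        """Adding a pure-noise covariate to a true model increases DIC in the
        majority of seeded replicates."""
        wins = 0
        n_rep = 12
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            n = 600
            x = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            eta = -0.5 + 0.8 * x
            y = (rng.uniform(size=n) < expit(eta)).astype(float)
            rows = pd.DataFrame({"x": x, "noise": noise, "y": y, "stratum": 1})
            kw = dict(n_iter=1200, n_burnin=400, n_chains=1, seed=seed)
            post1 = fit_mcmc(rows, ModelSpec(("x",), include_strata=False), **kw)
            post2 = fit_mcmc(
                rows, ModelSpec(("x", "noise"), include_strata=False), **kw
            )
            data1 = ModelData.from_rows(rows, ModelSpec(("x",), include_strata=False))
            data2 = ModelData.from_rows(
                rows, ModelSpec(("x", "noise"), include_strata=False)
            )
            wins += dic(post2, data2).dic > dic(post1, data1).dic
        assert wins > n_rep / 2
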