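"""Posterior density, sampler, DIC and coefficient summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import fhsae
from fhsae.links import get_link


class TestLinks:
    @pytest.mark.parametrize("name", ["identity", "log", "logit"])
    def test_round_trip(self, name):
        link = get_link(name)
        theta = np.linspace(0.001, 0.999, 200)
        assert np.allclose(link.inverse(link.transform(theta)), theta, atol=1e-12)

    def test_unknown_link(self):
        with pytest.raises(ValueError, match="unknown link"):
            get_link("probit")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(1e-3, 1 - 1e-3))
    def test_logit_round_trip_property(self, theta):
        link = get_link("logit")
        assert link.inverse(link.transform(theta)) == pytest.approx(theta, abs=1e-12)


def tiny_data(p, psi, X):
    return fhsae.FHData(p_direct=np.atleast_1d(p), psi=np.atleast_1d(psi),
                        X=np.atleast_2d(X))


class TestLogPosterior:
    def test_outside_prior_support(self):
        data = tiny_data(0.3, 0.01, [[1.0]])
        for s2 in (-0.1, 0.0, 1.5):
            assert fhsae.log_unnormalized_posterior(
                np.array([0.2]), s2, np.array([0.25]), data, "identity"
            ) == -np.inf

    def test_hand_evaluation_single_area(self):
        # two Gaussian log densities evaluated with scipy as the oracle
        data = tiny_data(0.3, 0.01, [[1.0]])
        got = fhsae.log_unnormalized_posterior(
            np.array([0.2]), 0.04, np.array([0.25]), data, "identity"
        )
        expected = (scipy.stats.norm.logpdf(0.3, 0.25, np.sqrt(0.01))
                    + scipy.stats.norm.logpdf(0.25, 0.2, np.sqrt(0.04)))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_additivity_under_duplication(self):
        rng = np.random.default_rng(1)
        m = 6
        X = np.column_stack([np.ones(m), rng.normal(size=m)])
        data = fhsae.FHData(rng.uniform(0.2, 0.5, m), rng.uniform(0.005, 0.02, m), X)
        data2 = fhsae.FHData(np.tile(data.p_direct, 2), np.tile(data.psi, 2),
                             np.vstack([X, X]))
        beta, s2 = np.array([0.1, 0.05]), 0.3
        theta = data.p_direct + 0.01
        lp1 = fhsae.log_unnormalized_posterior(beta, s2, theta, data, "logit")
        lp2 = fhsae.log_unnormalized_posterior(beta, s2, np.tile(theta, 2), data2, "logit")
        assert lp2 == pytest.approx(2 * lp1, rel=1e-12)

    def test_dimension_mismatch(self):
        data = tiny_data(0.3, 0.01, [[1.0]])
        with pytest.raises(ValueError, match="beta"):
            fhsae.log_unnormalized_posterior(
                np.array([0.2, 0.1]), 0.04, np.array([0.25]), data, "identity"
            )


class TestSampler:
    def test_tiny_psi_pins_theta_to_direct(self):
        rng = np.random.default_rng(2)
        m = 10
        X = np.column_stack([np.ones(m), rng.normal(size=m)])
        p = rng.uniform(0.2, 0.6, m)
        data = fhsae.FHData(p, np.full(m, 1e-8), X)
        s = fhsae.run_mcmc(data, "identity",
                           config=fhsae.MCMCConfig(n_iter=4000, burn_in=1000,
                                                   n_chains=1, seed=3,
                                                   proposal_sd=1e-4))
        assert np.allclose(s.theta.mean(axis=0), p, atol=1e-3)

    def test_matches_gls_oracle_with_fixed_variance(self, identity_fixture):
        data, _, sigma2 = identity_fixture
        prior = fhsae.PriorSpec(sigma2_fixed=sigma2)
        s = fhsae.run_mcmc(data, "identity", prior,
                           fhsae.MCMCConfig(n_iter=12000, burn_in=2000,
                                            n_chains=1, seed=4))
        # independent closed-form route: GLS normal equations by hand
        V = np.diag(data.psi + sigma2)
        Vinv = np.linalg.inv(V)
        cov = np.linalg.inv(data.X.T @ Vinv @ data.X)
        mean = cov @ data.X.T @ Vinv @ data.p_direct
        nb = 20
        batches = np.array_split(s.beta, nb)
        bm = np.array([b.mean(axis=0) for b in batches])
        mcse = bm.std(axis=0, ddof=1) / np.sqrt(nb)
        assert np.all(np.abs(s.beta.mean(axis=0) - mean) < 3 * mcse)
        assert np.allclose(s.beta.std(axis=0, ddof=1),
                           np.sqrt(np.diag(cov)), rtol=0.1)

    def test_split_chain_convergence(self, emdhs_fit):
        import arviz as az
        s = emdhs_fit["samples"]
        # rerun with 2 chains on the same data for the convergence check
        s2 = fhsae.run_mcmc(emdhs_fit["data"], "logit",
                            config=fhsae.MCMCConfig(n_iter=4000, burn_in=1000,
                                                    n_chains=2, seed=7))
        k = s2.beta.shape[1]
        per_chain = s2.beta.reshape(2, -1, k)
        rhat = az.rhat(az.convert_to_dataset(per_chain))["x"].values
        assert np.all(rhat < 1.05)
        assert s.theta.min() > 0 and s.theta.max() < 1  # logit-link support

    def test_shrinkage_convex_combination(self, identity_fixture):
        data, _, _ = identity_fixture
        s = fhsae.run_mcmc(data, "identity",
                           config=fhsae.MCMCConfig(n_iter=8000, burn_in=2000,
                                                   n_chains=1, seed=8))
        beta_hat = s.beta.mean(axis=0)
        synth = data.X @ beta_hat
        theta_hat = s.theta.mean(axis=0)
        lo = np.minimum(data.p_direct, synth) - 0.01
        hi = np.maximum(data.p_direct, synth) + 0.01
        assert np.all((theta_hat > lo) & (theta_hat < hi))

    def test_doubling_iterations_is_stable(self, emdhs_fit):
        data = emdhs_fit["data"]
        s1 = emdhs_fit["samples"]
        s2 = fhsae.run_mcmc(data, "logit",
                            config=fhsae.MCMCConfig(n_iter=6000, burn_in=600,
                                                    n_chains=1, seed=5))
        mcse = s1.beta.std(axis=0, ddof=1) / np.sqrt(200)  # conservative ESS
        assert np.all(np.abs(s1.beta.mean(axis=0) - s2.beta.mean(axis=0)) < 2 * mcse)

    def test_too_few_areas_errors(self):
        data = fhsae.FHData(np.array([0.3, 0.4]), np.array([0.01, 0.01]),
                            np.column_stack([np.ones(2), [0.1, 0.2]]))
        with pytest.raises(ValueError, match="sampled areas"):
            fhsae.run_mcmc(data, "identity")

    def test_out_of_domain_direct_estimate_errors(self):
        data = fhsae.FHData(np.array([1.2, 0.4, 0.3, 0.5]),
                            np.full(4, 0.01),
                            np.ones((4, 1)))
        with pytest.raises(ValueError, match="undefined"):
            fhsae.run_mcmc(data, "logit",
                           config=fhsae.MCMCConfig(n_iter=100, burn_in=10,
                                                   n_chains=1, seed=0))

    def test_reproducible_given_seed(self, emdhs_fit):
        data = emdhs_fit["data"]
        cfg = fhsae.MCMCConfig(n_iter=500, burn_in=100, n_chains=2, seed=13)
        a = fhsae.run_mcmc(data, "logit", config=cfg)
        b = fhsae.run_mcmc(data, "logit", config=cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.sigma2, b.sigma2)


class TestDIC:
    def two_area_data(self):
        return fhsae.FHData(np.array([0.3, 0.5]), np.array([0.01, 0.02]),
                            np.ones((2, 1)))

    def point_samples(self, theta_draws):
        theta_draws = np.asarray(theta_draws, dtype=float)
        n = theta_draws.shape[0]
        return fhsae.PosteriorSamples(
            beta=np.zeros((n, 1)), sigma2=np.full(n, 0.1),
            theta=theta_draws, mu=theta_draws,
            accept_rate=np.ones(theta_draws.shape[1]),
            chain_id=np.zeros(n, dtype=int), link="identity",
        )

    def test_zero_spread_gives_zero_pd(self):
        data = self.two_area_data()
        s = self.point_samples([[0.32, 0.48]] * 4)
        dic = fhsae.compute_dic(s, data)
        assert dic.pd == pytest.approx(0.0, abs=1e-10)
        assert dic.dic == pytest.approx(dic.dhat)

    def test_hand_computed_deviance_table(self):
        # 3 hand-written draws over 2 areas; oracle via scipy normal logpdf
        data = self.two_area_data()
        draws = np.array([[0.28, 0.47], [0.31, 0.52], [0.34, 0.49]])
        s = self.point_samples(draws)
        dic = fhsae.compute_dic(s, data)
        sd = np.sqrt(data.psi)
        d_each = [-2 * scipy.stats.norm.logpdf(data.p_direct, row, sd).sum()
                  for row in draws]
        dbar = np.mean(d_each)
        dhat = -2 * scipy.stats.norm.logpdf(data.p_direct, draws.mean(axis=0), sd).sum()
        assert dic.dbar == pytest.approx(dbar, abs=1e-10)
        assert dic.dhat == pytest.approx(dhat, abs=1e-10)
        assert dic.pd == pytest.approx(dbar - dhat, abs=1e-10)
        assert dic.dic == pytest.approx(2 * dbar - dhat, abs=1e-10)

    def test_deviance_additivity_under_duplication(self):
        data = self.two_area_data()
        data2 = fhsae.FHData(np.tile(data.p_direct, 2), np.tile(data.psi, 2),
                             np.ones((4, 1)))
        draws = np.array([[0.28, 0.47], [0.31, 0.52], [0.34, 0.49]])
        s1 = self.point_samples(draws)
        s2 = self.point_samples(np.hstack([draws, draws]))
        d1 = fhsae.compute_dic(s1, data)
        d2 = fhsae.compute_dic(s2, data2)
        assert d2.dbar == pytest.approx(2 * d1.dbar)
        assert d2.dhat == pytest.approx(2 * d1.dhat)

    def test_dic_identity_on_real_fit(self, emdhs_fit):
        dic = fhsae.compute_dic(emdhs_fit["samples"], emdhs_fit["data"])
        assert dic.dic == pytest.approx(2 * dic.dbar - dic.dhat, abs=1e-9)


class TestCompareLinks:
    def test_singleton_returns_that_link(self, emdhs_fit):
        cfg = fhsae.MCMCConfig(n_iter=400, burn_in=100, n_chains=1, seed=1)
        tab = fhsae.compare_links(emdhs_fit["data"], config=cfg, links=("logit",))
        assert list(tab["link"]) == ["logit"]
        assert tab["best"].iloc[0]

    def test_identical_links_identical_dic(self, emdhs_fit):
        cfg = fhsae.MCMCConfig(n_iter=400, burn_in=100, n_chains=1, seed=1)
        tab = fhsae.compare_links(emdhs_fit["data"], config=cfg,
                                  links=("logit", "logit"))
        assert tab["dic"].iloc[0] == tab["dic"].iloc[1]

    def test_inestimable_link_reported_not_fatal(self):
        # direct estimate above 1 leaves logit/log-scale init undefined
        data = fhsae.FHData(np.array([1.2, 0.4, 0.3, 0.5, 0.6]),
                            np.full(5, 0.01), np.ones((5, 1)))
        cfg = fhsae.MCMCConfig(n_iter=300, burn_in=50, n_chains=1, seed=2)
        tab = fhsae.compare_links(data, config=cfg)
        row = tab.set_index("link")
        assert not row.loc["logit", "estimable"]
        assert row.loc["identity", "estimable"]
        best = tab.loc[tab["best"], "link"].iloc[0]
        assert row.loc[best, "estimable"]


class TestCoefficientSummary:
    def summaries_for(self, draws):
        draws = np.asarray(draws, dtype=float).reshape(-1, 1)
        s = fhsae.PosteriorSamples(
            beta=draws, sigma2=np.full(len(draws), 0.1),
            theta=np.full((len(draws), 1), 0.5),
            mu=np.zeros((len(draws), 1)),
            accept_rate=np.ones(1), chain_id=np.zeros(len(draws), dtype=int),
        )
        return fhsae.summarize_coefficients(s).iloc[0]

    def test_point_mass(self):
        row = self.summaries_for([2.0] * 10)
        assert row["mean"] == 2.0 and row["sd"] == 0.0
        assert row["ci_low"] == row["ci_high"] == 2.0
        assert row["significant"]
        zero = self.summaries_for([0.0] * 10)
        assert not zero["significant"]

    def test_symmetric_draws_not_significant(self):
        row = self.summaries_for(np.linspace(-1, 1, 101))
        assert row["ci_low"] < 0 < row["ci_high"]
        assert not row["significant"]

    def test_gaussian_quantile_oracle(self):
        rng = np.random.default_rng(9)
        row = self.summaries_for(rng.normal(2.0, 1.0, 10_000))
        assert row["mean"] == pytest.approx(2.0, abs=0.05)
        assert row["ci_low"] == pytest.approx(2 - 1.96, abs=0.08)
        assert row["ci_high"] == pytest.approx(2 + 1.96, abs=0.08)
        assert row["significant"]
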