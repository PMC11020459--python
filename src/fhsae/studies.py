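"""Replicated simulation studies over the study-scale synthetic scenario.

Each study simulates fresh data from the default generator, runs the
relevant stage of the pipeline and returns the raw per-replicate
measurements, leaving pass/fail judgements to the caller.  Problem sizes
default to scaled-down settings that keep a full battery within a few
minutes on one core.

Raw design variances are fed to the sampler in the recovery and
link-selection studies: the GVF regression omits log(n_i), so its
smoothed variances are systematically mis-calibrated per area when
sample sizes vary widely, which would confound checks aimed at the
sampler itself.  The efficiency study uses the GVF-smoothed pipeline
default, matching the workflow the estimates are produced with.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .diagnostics import bias_diagnostic, cv_comparison_table, summarize_sampled
from .direct import compute_direct
from .gvf import fit_gvf, select_variance
from .hb import FHData, MCMCConfig, compare_links, run_mcmc, summarize_coefficients
from .pipeline import make_fh_data
from .synthetic import emdhs_like_config, simulate_areas


def _fit_replicate(seed, rep, n_iter, burn_in, variance_mode="raw", link="logit"):
    cfg = emdhs_like_config(seed=int(seed + rep))
    table, truth = simulate_areas(cfg)
    direct = compute_direct(table)
    gvf = fit_gvf(direct) if variance_mode == "gvf" else None
    psi = select_variance(direct, gvf, variance_mode)
    data = make_fh_data(table, direct, psi)
    mcmc = MCMCConfig(n_iter=n_iter, burn_in=burn_in, n_chains=1,
                      seed=int(seed * 7919 + rep) % (2**31 - 1))
    samples = run_mcmc(data, link, config=mcmc)
    return cfg, table, truth, direct, data, samples, mcmc


def gls_agreement_study(seed: int = 0, m: int = 40, n_draws: int = 20_000,
                        n_batches: int = 40) -> dict:
    """Identity link, variance fixed: MCMC vs the closed-form GLS posterior.

    Returns the MCMC and GLS posterior means and covariances of beta plus
    batch-means Monte-Carlo standard errors for both summaries.
    """
    from .hb import PriorSpec, gls_beta_posterior

    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(m), rng.uniform(-1, 1, (m, 2))])
    beta_true = np.array([0.35, 0.10, -0.15])
    sigma2 = 0.02
    theta = X @ beta_true + rng.normal(0, np.sqrt(sigma2), m)
    psi = rng.uniform(0.004, 0.015, m)
    p = theta + rng.normal(0, np.sqrt(psi))
    data = FHData(p_direct=p, psi=psi, X=X)

    burn = max(2000, n_draws // 10)
    samples = run_mcmc(
        data, "identity", PriorSpec(sigma2_fixed=sigma2),
        MCMCConfig(n_iter=n_draws + burn, burn_in=burn, n_chains=1,
                   seed=seed + 1),
    )
    gls_mean, gls_cov = gls_beta_posterior(X, p, psi, sigma2)

    batches = np.array_split(samples.beta, n_batches)
    bmeans = np.array([b.mean(axis=0) for b in batches])
    bcovs = np.array([np.cov(b, rowvar=False, ddof=1) for b in batches])
    return {
        "mcmc_mean": samples.beta.mean(axis=0),
        "gls_mean": gls_mean,
        "mean_mcse": bmeans.std(axis=0, ddof=1) / np.sqrt(n_batches),
        "mcmc_cov": np.cov(samples.beta, rowvar=False, ddof=1),
        "gls_cov": gls_cov,
        "cov_mcse": bcovs.std(axis=0, ddof=1) / np.sqrt(n_batches),
    }


def recovery_study(seed: int = 0, n_reps: int = 100, n_iter: int = 5_000,
                   burn_in: int = 1_000) -> dict:
    """Logit-link parameter recovery at study scale.

    Per replicate: simulate, fit, record whether each true beta component
    falls in its 95% credible interval and the posterior mean of the
    area-effect variance.
    """
    covered = []
    sigma2_means = []
    for rep in range(n_reps):
        cfg, _, _, _, _, samples, _ = _fit_replicate(seed, rep, n_iter, burn_in)
        summ = summarize_coefficients(samples)
        bt = np.asarray(cfg.beta_true)
        covered.append(
            (summ["ci_low"].to_numpy() <= bt) & (bt <= summ["ci_high"].to_numpy())
        )
        sigma2_means.append(float(samples.sigma2.mean()))
    covered = np.array(covered)
    sigma2_means = np.array(sigma2_means)
    return {
        "coverage": covered.mean(axis=0),
        "sigma2_true": emdhs_like_config().sigma2_nu_true,
        "sigma2_post_means": sigma2_means,
        "sigma2_mean": float(sigma2_means.mean()),
        "sigma2_se": float(sigma2_means.std(ddof=1) / np.sqrt(n_reps)),
    }


def link_selection_study(seed: int = 0, n_reps: int = 20, n_iter: int = 6_000,
                         burn_in: int = 1_200) -> dict:
    """How often DIC picks the generating (logit) link."""
    winners = []
    for rep in range(n_reps):
        cfg = emdhs_like_config(seed=int(seed + rep))
        table, _ = simulate_areas(cfg)
        direct = compute_direct(table)
        psi = select_variance(direct, None, "raw")
        data = make_fh_data(table, direct, psi)
        mcmc = MCMCConfig(n_iter=n_iter, burn_in=burn_in, n_chains=1,
                          seed=int(seed * 104729 + rep) % (2**31 - 1))
        tab = compare_links(data, config=mcmc)
        winners.append(tab.loc[tab["best"], "link"].iloc[0])
    winners = np.array(winners)
    return {
        "winners": winners,
        "logit_wins": int((winners == "logit").sum()),
        "n_reps": n_reps,
    }


def efficiency_study(seed: int = 0, n_reps: int = 50, n_iter: int = 3_000,
                     burn_in: int = 600) -> dict:
    """Precision gain of HB over direct estimates, GVF-smoothed pipeline.

    Records the mean percent CV of direct and HB estimates and the
    bias-diagnostic slope per replicate.
    """
    mean_direct_cv, mean_hb_cv, slopes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for rep in range(n_reps):
            _, table, _, direct, _, samples, _ = _fit_replicate(
                seed, rep, n_iter, burn_in, variance_mode="gvf"
            )
            est = summarize_sampled(samples, table.area_ids[table.sampled])
            tab = cv_comparison_table(direct, est)
            row = tab.set_index("quantity").loc["Mean"]
            mean_direct_cv.append(float(row["direct_cv"]))
            mean_hb_cv.append(float(row["hb_cv"]))
            slopes.append(bias_diagnostic(direct, est).slope)
    mean_direct_cv = np.array(mean_direct_cv)
    mean_hb_cv = np.array(mean_hb_cv)
    return {
        "mean_direct_cv": mean_direct_cv,
        "mean_hb_cv": mean_hb_cv,
        "hb_more_precise_frac": float((mean_hb_cv < mean_direct_cv).mean()),
        "slopes": np.array(slopes),
    }
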