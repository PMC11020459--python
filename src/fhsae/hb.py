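"""Hierarchical-Bayes Fay-Herriot fitting by Metropolis-within-Gibbs.

The area-level model has two stages.  Sampling model: the direct
estimate ``p_i`` is Normal around the true proportion ``theta_i`` with
known design variance ``psi_i``.  Linking model: ``link(theta_i)`` is
Normal around ``x_i' beta`` with area-effect variance ``sigma2_nu``.
Three links are supported — identity (the matched Fay-Herriot model),
log and logit (unmatched models for proportions).

Priors follow the standard non-informative choice for this model class:
flat on ``beta`` and Uniform(0, upper) on the variance ``sigma2_nu``
(default upper = 1).  The sampler alternates

* an exact Gaussian draw of ``beta`` from its full conditional
  (flat prior => N((X'X)^-1 X' mu, sigma2_nu (X'X)^-1)),
* per-area random-walk Metropolis on the link scale ``mu_i``
  (the conditional factorises over areas, so all areas update in one
  vectorised step),
* an inverse-CDF draw of ``sigma2_nu`` from its truncated
  inverse-gamma-shaped full conditional on (0, upper).

Proposal scales adapt toward 0.44 acceptance during burn-in only
(Robbins-Monro), so detailed balance holds for every retained draw.

Model choice uses DIC computed on the sampling model: deviance
``D(theta) = -2 sum_i log N(p_i; theta_i, psi_i)``, effective parameters
``pD = Dbar - D(theta_bar)`` with the plug-in at the proportion-scale
posterior mean, and ``DIC = Dbar + pD``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaincc, gammainccinv

from .links import LinkSpec, get_link

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# configuration containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Flat prior on beta; Uniform(0, sigma2_upper) on the variance.

    ``sigma2_fixed`` collapses the variance prior to a point mass — used
    for closed-form cross-checks of the sampler, not for analysis.
    """

    sigma2_upper: float = 1.0
    sigma2_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2_upper <= 0:
            raise ValueError(f"sigma2_upper must be > 0, got {self.sigma2_upper}")
        if self.sigma2_fixed is not None and self.sigma2_fixed <= 0:
            raise ValueError("sigma2_fixed must be > 0 when set")


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 1
    n_chains: int = 2
    seed: int = 0
    proposal_sd: float = 0.5
    adapt: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")


@dataclass
class FHData:
    """Sampled-area inputs to the sampling/linking model."""

    p_direct: np.ndarray      # direct proportions, corrected
    psi: np.ndarray           # known sampling variances (raw or smoothed)
    X: np.ndarray             # design matrix, intercept first
    area_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p_direct = np.asarray(self.p_direct, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        m = self.p_direct.shape[0]
        if self.psi.shape != (m,) or self.X.shape[0] != m:
            raise ValueError("p_direct, psi and X rows must align")
        if np.any(self.psi <= 0):
            raise ValueError("psi must be strictly positive")
        if self.area_ids is None:
            self.area_ids = np.arange(m)

    @property
    def m(self) -> int:
        return self.p_direct.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, chains concatenated in order."""

    beta: np.ndarray          # draws x (p+1)
    sigma2: np.ndarray        # draws
    theta: np.ndarray         # draws x m, proportion scale
    mu: np.ndarray            # draws x m, link scale
    accept_rate: np.ndarray   # per-area acceptance after burn-in
    chain_id: np.ndarray      # per-draw chain label
    link: str = "logit"
    coef_names: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_draws else 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (chain, iteration, parameter, value)."""
        names = self.coef_names or [f"beta{j}" for j in range(self.beta.shape[1])]
        frames = []
        for chain in range(self.n_chains):
            sel = self.chain_id == chain
            it = np.arange(int(sel.sum()))
            cols = {name: self.beta[sel, j] for j, name in enumerate(names)}
            cols["sigma2_nu"] = self.sigma2[sel]
            for i in range(self.theta.shape[1]):
                cols[f"theta[{i}]"] = self.theta[sel, i]
            long = (
                pd.DataFrame(cols)
                .assign(chain=chain, iteration=it)
                .melt(id_vars=["chain", "iteration"],
                      var_name="parameter", value_name="value")
            )
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


@dataclass
class DICResult:
    dbar: float
    dhat: float
    pd: float
    dic: float


# --------------------------------------------------------------------------
# densities
# --------------------------------------------------------------------------

def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var)) - (x - mean) ** 2 / (2.0 * var)


def log_unnormalized_posterior(
    beta: np.ndarray,
    sigma2: float,
    theta_vec: np.ndarray,
    data: FHData,
    link: str | LinkSpec,
    prior: PriorSpec | None = None,
) -> float:
    """Joint log posterior density up to an additive constant.

    Sum of the sampling-model Gaussian log densities of the direct
    estimates, the linking-model Gaussian log densities of the
    link-transformed true proportions, and the log priors (flat beta;
    uniform variance, so -inf outside (0, upper)).
    """
    link = get_link(link)
    prior = prior or PriorSpec()
    beta = np.asarray(beta, dtype=float)
    theta_vec = np.asarray(theta_vec, dtype=float)
    if beta.shape[0] != data.k:
        raise ValueError(
            f"beta has length {beta.shape[0]}, design has {data.k} columns"
        )
    upper = prior.sigma2_upper
    if prior.sigma2_fixed is None and not 0.0 < sigma2 < upper:
        return -np.inf
    if not np.all(link.in_domain(theta_vec)):
        return -np.inf
    mu = link.transform(theta_vec)
    ll_sampling = _norm_logpdf(data.p_direct, theta_vec, data.psi).sum()
    ll_linking = _norm_logpdf(mu, data.X @ beta, sigma2).sum()
    return float(ll_sampling + ll_linking)


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

def _draw_sigma2(rng, resid_ss: float, m: int, upper: float) -> float:
    # truncated inverse-gamma via the precision: tau ~ Gamma(m/2 - 1, rate SS/2)
    # restricted to tau >= 1/upper, drawn by inverse upper-tail CDF
    a = 0.5 * m - 1.0
    b = 0.5 * resid_ss
    if a <= 0.0:
        raise ValueError("sigma2 full conditional needs at least 3 areas")
    sf0 = gammaincc(a, b / upper)
    if sf0 <= 0.0 or not np.isfinite(sf0):
        return upper * (1.0 - 1e-12)
    u = rng.uniform(0.0, sf0)
    tau = gammainccinv(a, u) / b
    return float(min(1.0 / tau, upper * (1.0 - 1e-12)))


def _run_single_chain(data, link, prior, config, rng, init_beta, init_mu):
    m, k = data.m, data.k
    X, p_dir, psi = data.X, data.p_direct, data.psi
    upper = prior.sigma2_upper
    fixed = prior.sigma2_fixed

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    proj = XtX_inv @ X.T              # OLS projector for the beta conditional
    L = np.linalg.cholesky(XtX_inv)

    beta = init_beta.copy()
    mu = init_mu.copy()
    theta = link.inverse(mu)
    sigma2 = fixed if fixed is not None else upper / 2.0

    lp0 = (_norm_logpdf(p_dir, theta, psi) + _norm_logpdf(mu, X @ beta, sigma2)).sum()
    if not np.isfinite(lp0):
        raise RuntimeError(
            "non-finite log posterior at initialization; re-initialize "
            "(check that direct estimates lie in the link's domain)"
        )

    n_keep = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    out_beta = np.empty((n_keep, k))
    out_sigma2 = np.empty(n_keep)
    out_theta = np.empty((n_keep, m))
    out_mu = np.empty((n_keep, m))

    log_s = np.full(m, np.log(config.proposal_sd))
    acc_count = np.zeros(m)
    kept = 0

    # cache the per-area log target pieces for the Metropolis ratio
    samp_ll = _norm_logpdf(p_dir, theta, psi)

    for t in range(config.n_iter):
        # (a) beta | mu, sigma2 — exact Gaussian full conditional
        beta_hat = proj @ mu
        beta = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(k))
        xb = X @ beta

        # (b) mu_i | rest — vectorised random-walk Metropolis
        prop = mu + np.exp(log_s) * rng.standard_normal(m)
        theta_prop = link.inverse(prop)
        samp_ll_prop = _norm_logpdf(p_dir, theta_prop, psi)
        log_ratio = (samp_ll_prop - samp_ll) + (
            _norm_logpdf(prop, xb, sigma2) - _norm_logpdf(mu, xb, sigma2)
        )
        accept = np.log(rng.uniform(size=m)) < log_ratio
        mu = np.where(accept, prop, mu)
        theta = np.where(accept, theta_prop, theta)
        samp_ll = np.where(accept, samp_ll_prop, samp_ll)

        if config.adapt and t < config.burn_in:
            step = (t + 1.0) ** -0.6
            log_s += step * (accept.astype(float) - 0.44)
        else:
            acc_count += accept

        # (c) sigma2 | mu, beta — truncated inverse-gamma, inverse-CDF
        if fixed is None:
            resid_ss = float(((mu - xb) ** 2).sum())
            sigma2 = _draw_sigma2(rng, resid_ss, m, upper)

        if t >= config.burn_in and (t - config.burn_in) % config.thin == 0:
            out_beta[kept] = beta
            out_sigma2[kept] = sigma2
            out_theta[kept] = theta
            out_mu[kept] = mu
            kept += 1

    post_iters = config.n_iter - config.burn_in
    acc_rate = acc_count / max(post_iters, 1)
    return out_beta[:kept], out_sigma2[:kept], out_theta[:kept], out_mu[:kept], acc_rate


def _initialize(data: FHData, link: LinkSpec):
    if not np.all(link.in_domain(data.p_direct)):
        bad = np.flatnonzero(~link.in_domain(data.p_direct))
        raise ValueError(
            f"link {link.name!r} undefined for direct estimates of areas "
            f"{bad.tolist()}"
        )
    mu0 = link.transform(data.p_direct)
    beta0, *_ = np.linalg.lstsq(data.X, mu0, rcond=None)
    return beta0, mu0


def run_mcmc(
    data: FHData,
    link: str | LinkSpec = "logit",
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    coef_names: list[str] | None = None,
) -> PosteriorSamples:
    """Fit one Fay-Herriot HB model and return retained posterior draws.

    Chains are seeded independently from ``config.seed`` via spawned
    seed sequences; draws are concatenated with a per-draw chain label.
    A per-area post-burn-in acceptance rate below 0.05 triggers a
    warning in the run log.
    """
    link = get_link(link)
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    if data.m < data.k + 1:
        raise ValueError(
            f"need at least p + 2 = {data.k + 1} sampled areas, got {data.m}"
        )

    beta0, mu0 = _initialize(data, link)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    chunks = []
    acc = np.zeros(data.m)
    for chain, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        b, s2, th, mu, a = _run_single_chain(
            data, link, prior, config, rng, beta0, mu0
        )
        chunks.append((b, s2, th, mu, np.full(b.shape[0], chain)))
        acc += a
    acc /= config.n_chains

    low = np.flatnonzero(acc < 0.05)
    if low.size:
        msg = f"acceptance rate below 0.05 for areas {low.tolist()}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    names = coef_names or [f"beta{j}" for j in range(data.k)]
    return PosteriorSamples(
        beta=np.vstack([c[0] for c in chunks]),
        sigma2=np.concatenate([c[1] for c in chunks]),
        theta=np.vstack([c[2] for c in chunks]),
        mu=np.vstack([c[3] for c in chunks]),
        accept_rate=acc,
        chain_id=np.concatenate([c[4] for c in chunks]).astype(int),
        link=link.name,
        coef_names=names,
    )


# --------------------------------------------------------------------------
# DIC and model comparison
# --------------------------------------------------------------------------

def deviance(theta: np.ndarray, data: FHData) -> np.ndarray:
    """Sampling-model deviance -2 sum_i log N(p_i; theta_i, psi_i).

    Accepts a single theta vector or a draws x m matrix.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    ll = _norm_logpdf(data.p_direct[None, :], theta, data.psi[None, :]).sum(axis=1)
    return -2.0 * ll


def compute_dic(samples: PosteriorSamples, data: FHData) -> DICResult:
    if samples.n_draws == 0:
        raise ValueError("empty posterior samples")
    d = deviance(samples.theta, data)
    dbar = float(d.mean())
    theta_bar = samples.theta.mean(axis=0)
    dhat = float(deviance(theta_bar, data)[0])
    pd_eff = dbar - dhat
    return DICResult(dbar=dbar, dhat=dhat, pd=pd_eff, dic=dbar + pd_eff)


def compare_links(
    data: FHData,
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    links: tuple[str, ...] = ("identity", "log", "logit"),
) -> pd.DataFrame:
    """Fit each candidate link with the same data/prior/MCMC budget.

    Returns a table sorted by DIC (ascending) with a ``best`` flag on the
    minimiser.  A link whose likelihood is undefined for the observed
    direct estimates is reported with NaN DIC and ``estimable = False``
    rather than aborting the comparison.
    """
    rows = []
    fits = {}
    for name in links:
        try:
            samples = run_mcmc(data, link=name, prior=prior, config=config)
            dic = compute_dic(samples, data)
            rows.append(
                {"link": name, "dic": dic.dic, "dbar": dic.dbar,
                 "dhat": dic.dhat, "pd": dic.pd, "estimable": True}
            )
            fits[name] = samples
        except (ValueError, RuntimeError, FloatingPointError) as exc:
            logger.warning("link %s inestimable: %s", name, exc)
            rows.append(
                {"link": name, "dic": np.nan, "dbar": np.nan,
                 "dhat": np.nan, "pd": np.nan, "estimable": False}
            )
    table = pd.DataFrame(rows).sort_values(
        "dic", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    table["best"] = False
    if table["estimable"].any():
        table.loc[0, "best"] = True
    table.attrs["fits"] = fits
    return table


def summarize_coefficients(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean, SD and equal-tailed 95% credible interval per beta.

    ``significant`` is True when the interval excludes zero.
    """
    if samples.n_draws == 0:
        raise ValueError("empty posterior samples")
    draws = samples.beta
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1) if draws.shape[0] > 1 else np.zeros(draws.shape[1])
    names = samples.coef_names or [f"beta{j}" for j in range(draws.shape[1])]
    return pd.DataFrame(
        {
            "coefficient": names,
            "mean": mean,
            "sd": sd,
            "ci_low": lo,
            "ci_high": hi,
            "significant": (lo > 0.0) | (hi < 0.0),
        }
    )


def gls_beta_posterior(
    X: np.ndarray, p: np.ndarray, psi: np.ndarray, sigma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form beta posterior for the matched (identity-link) model.

    With sigma2 fixed and theta integrated out, ``p ~ N(X beta, V)`` with
    ``V = diag(psi + sigma2)``; under the flat prior the posterior of
    beta is Gaussian with the GLS mean ``(X'V^-1 X)^-1 X'V^-1 p`` and
    covariance ``(X'V^-1 X)^-1``.
    """
    w = 1.0 / (np.asarray(psi, dtype=float) + sigma2)
    Xw = X * w[:, None]
    cov = np.linalg.inv(X.T @ Xw)
    mean = cov @ (Xw.T @ p)
    return mean, cov
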