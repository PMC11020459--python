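"""Synthetic area-level survey + census data generator.

Emulates the structure of a zone-level binary-indicator study: ``m``
areas, a census-style covariate matrix of proportions, Gaussian area
random effects on the link scale, binomial counts within sampled areas
and a fixed fraction of non-sampled areas (zero survey sample but known
covariates and population).

The default scenario mirrors the motivating application: 83 zones of
which 6 are non-sampled, 8 auxiliary covariates, logit link, area-effect
variance 0.3243 and coefficients placed so that the average prevalence is
about 0.28 — the national coverage of community-based health insurance
the study targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .areas import AreaTable
from .links import LinkSpec, get_link


class ConfigurationError(ValueError):
    """A synthetic configuration field is invalid."""


class SimulationError(RuntimeError):
    """The generative model produced invalid proportions."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative area-level model.

    Parameters
    ----------
    m : int
        Number of areas (>= 2).
    p : int
        Number of covariates excluding the intercept (>= 0; realistic
        scenarios use at least one, but an intercept-only design is
        accepted for testing).
    beta_true : tuple of float
        Length ``p + 1`` coefficient vector, intercept first, on the link
        scale.
    sigma2_nu_true : float
        Variance of the Gaussian area random effects (>= 0), link scale.
    link : str
        "identity", "log" or "logit".
    n_min, n_max : int
        Area sample sizes are drawn integer-uniform on [n_min, n_max].
    frac_nonsampled : float
        Fraction in [0, 1) of areas forced to ``n_i = 0``.
    pop_size : int
        Constant area population size ``N_i`` (must exceed ``n_max``).
    seed : int
        RNG seed; one generator drives the whole simulation.
    """

    m: int = 83
    p: int = 8
    beta_true: tuple[float, ...] = (
        -0.94, 1.2, -0.8, 0.6, -0.5, 0.4, -0.3, 0.8, -0.6,
    )
    sigma2_nu_true: float = 0.3243
    link: str = "logit"
    n_min: int = 15
    n_max: int = 120
    frac_nonsampled: float = 6 / 83
    pop_size: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ConfigurationError(f"m must be >= 2, got {self.m}")
        if self.p < 0:
            raise ConfigurationError(f"p must be >= 0, got {self.p}")
        if len(self.beta_true) != self.p + 1:
            raise ConfigurationError(
                f"beta_true must have length p + 1 = {self.p + 1}, "
                f"got {len(self.beta_true)}"
            )
        if self.sigma2_nu_true < 0:
            raise ConfigurationError(
                f"sigma2_nu_true must be >= 0, got {self.sigma2_nu_true}"
            )
        if not 0 <= self.frac_nonsampled < 1:
            raise ConfigurationError(
                f"frac_nonsampled must be in [0, 1), got {self.frac_nonsampled}"
            )
        if not 0 < self.n_min <= self.n_max:
            raise ConfigurationError(
                f"need 0 < n_min <= n_max, got [{self.n_min}, {self.n_max}]"
            )
        if self.pop_size <= self.n_max:
            raise ConfigurationError(
                f"pop_size must exceed n_max, got {self.pop_size}"
            )
        get_link(self.link)


def emdhs_like_config(**overrides) -> SyntheticConfig:
    """The default study-scale scenario, optionally overridden per field."""
    return replace(SyntheticConfig(), **overrides)


@dataclass(frozen=True)
class SyntheticTruth:
    """Realized simulation truth, parallel to the area table rows."""

    p_true: np.ndarray
    nu_true: np.ndarray
    mu_true: np.ndarray = field(repr=False)

    def to_frame(self, area_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": area_ids,
                "p_true": self.p_true,
                "nu_true": self.nu_true,
                "mu_true": self.mu_true,
            }
        )


def generate_covariates(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """m x (p+1) design matrix: intercept column, then centred U(0,1) draws.

    Covariates imitate census shares in [0, 1]; they are centred
    column-wise after generation so the intercept stays interpretable as
    the link-scale prevalence of a typical area.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.ones((config.m, config.p + 1))
    if config.p > 0:
        raw = rng.uniform(0.0, 1.0, size=(config.m, config.p))
        X[:, 1:] = raw - raw.mean(axis=0)
    return X


def simulate_areas(
    config: SyntheticConfig,
) -> tuple[AreaTable, SyntheticTruth]:
    """Draw one synthetic study: covariates, truth, counts, sampled flags.

    The generative model is
    ``nu_i ~ N(0, sigma2_nu)``, ``P_i = inverse-link(x_i' beta + nu_i)``,
    ``y_i ~ Binomial(n_i, P_i)`` for sampled areas.  For the log and
    identity links an inverse-linked proportion outside (0, 1) raises
    :class:`SimulationError` listing the offending areas — the generator
    never clamps, since silent truncation would corrupt
    parameter-recovery checks downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    link: LinkSpec = get_link(config.link)

    X = generate_covariates(config, rng)
    beta = np.asarray(config.beta_true, dtype=float)
    nu = rng.normal(0.0, np.sqrt(config.sigma2_nu_true), size=config.m)
    mu = X @ beta + nu
    p_true = link.inverse(mu)

    bad = np.flatnonzero((p_true <= 0.0) | (p_true >= 1.0))
    if bad.size:
        raise SimulationError(
            f"link {config.link!r}: inverse-linked proportion outside (0,1) "
            f"for areas {bad.tolist()} (values {p_true[bad].round(4).tolist()})"
        )

    n = rng.integers(config.n_min, config.n_max + 1, size=config.m)
    k_zero = int(round(config.frac_nonsampled * config.m))
    if k_zero:
        nonsampled_idx = rng.choice(config.m, size=k_zero, replace=False)
        n[nonsampled_idx] = 0
    y = np.where(n > 0, rng.binomial(np.maximum(n, 1), p_true), 0)

    df = pd.DataFrame(
        {
            "area_id": [f"zone_{i + 1:03d}" for i in range(config.m)],
            "n": n.astype(int),
            "y": y.astype(int),
            "N": np.full(config.m, config.pop_size, dtype=int),
        }
    )
    for j in range(config.p):
        df[f"x{j + 1}"] = X[:, j + 1]
    df["p_true"] = p_true
    df["nu_true"] = nu

    return AreaTable(df), SyntheticTruth(p_true=p_true, nu_true=nu, mu_true=mu)
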