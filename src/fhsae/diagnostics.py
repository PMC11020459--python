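"""Per-area HB estimates and the model-checking battery.

Covers: posterior summaries for sampled areas, posterior-predictive
(synthetic) estimates for non-sampled areas, the bias-diagnostic
regression of direct on model-based estimates, Shapiro-Wilk normality of
linking-model residuals with Q-Q coordinates, and the CV comparison /
efficiency-gain table that quantifies the precision the model buys over
the direct survey estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .direct import DirectEstimates
from .hb import FHData, PosteriorSamples
from .links import get_link

CV_ROWS = ("Minimum", "1st quartile", "Median", "Mean", "3rd quartile", "Maximum")


@dataclass
class BiasDiagnostic:
    slope: float
    intercept: float
    fitted: np.ndarray   # fitted line evaluated at the model-based estimates


@dataclass
class NormalityResult:
    shapiro_w: float
    shapiro_p: float
    residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray


def _summaries(draws: np.ndarray, area_ids, sampled_flag: bool) -> pd.DataFrame:
    """Mean/SD/CI/CV over a draws x m matrix of proportion-scale values."""
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1) if draws.shape[0] > 1 else np.zeros(draws.shape[1])
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    return pd.DataFrame(
        {
            "area_id": np.asarray(area_ids),
            "hb_mean": mean,
            "hb_sd": sd,
            "ci_low": lo,
            "ci_high": hi,
            "hb_cv": cv,
            "sampled": sampled_flag,
        }
    )


def summarize_sampled(samples: PosteriorSamples, area_ids=None) -> pd.DataFrame:
    """AreaEstimate rows (posterior mean, SD, 95% CI, percent CV) per
    sampled area, computed on the proportion scale."""
    if samples.n_draws == 0:
        raise ValueError("empty posterior samples")
    m = samples.theta.shape[1]
    if area_ids is None:
        area_ids = np.arange(m)
    return _summaries(samples.theta, area_ids, sampled_flag=True)


def predict_nonsampled(
    samples: PosteriorSamples,
    X_new: np.ndarray,
    area_ids=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-predictive estimates for areas with no survey sample.

    For each retained draw ``(beta, sigma2_nu)`` a fresh area effect
    ``nu* ~ N(0, sigma2_nu)`` is drawn and ``theta* = inverse-link(x'beta
    + nu*)``; summaries are over these predictive draws, so the CV
    reflects both parameter and area-effect uncertainty (a non-sampled
    area is never more precise than a sampled one with the same
    covariates).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != samples.beta.shape[1]:
        raise ValueError(
            f"covariate rows have {X_new.shape[1]} columns, fitted design "
            f"has {samples.beta.shape[1]}"
        )
    if np.any(~np.isfinite(X_new)):
        bad = np.flatnonzero(~np.isfinite(X_new).all(axis=1))
        ids = np.asarray(area_ids)[bad] if area_ids is not None else bad
        raise ValueError(f"missing covariates for areas {ids.tolist()}")
    link = get_link(samples.link)
    rng = np.random.default_rng(seed)
    n_draws = samples.n_draws
    n_new = X_new.shape[0]
    if area_ids is None:
        area_ids = np.arange(n_new)
    eta = samples.beta @ X_new.T                      # draws x n_new
    nu_star = rng.standard_normal((n_draws, n_new)) * np.sqrt(
        samples.sigma2[:, None]
    )
    theta_star = link.inverse(eta + nu_star)
    return _summaries(theta_star, area_ids, sampled_flag=False)


def bias_diagnostic(direct: DirectEstimates, hb: pd.DataFrame) -> BiasDiagnostic:
    """OLS of direct estimates on HB means over sampled areas.

    A slope near 1 and intercept near 0 indicates the model-based
    estimates track the design-unbiased direct estimates.
    """
    y = direct.p
    x = hb.loc[hb["sampled"], "hb_mean"].to_numpy(dtype=float)
    if y.shape[0] < 3:
        raise ValueError("bias diagnostic needs >= 3 sampled areas")
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in HB means: slope unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    return BiasDiagnostic(
        slope=float(slope), intercept=float(intercept),
        fitted=np.asarray(res.fittedvalues),
    )


def residual_normality(
    samples: PosteriorSamples, data: FHData
) -> NormalityResult:
    """Shapiro-Wilk test of the linking-model residuals.

    Residuals are ``link(theta_hat_i) - x_i' beta_hat`` at the posterior
    means — the realized area effects the linking model asserts are
    Gaussian.  Also returns Q-Q plot coordinates.
    """
    link = get_link(samples.link)
    theta_hat = samples.theta.mean(axis=0)
    beta_hat = samples.beta.mean(axis=0)
    r = link.transform(theta_hat) - data.X @ beta_hat
    if r.shape[0] < 3:
        raise ValueError("normality test needs >= 3 residuals")
    if np.ptp(r) == 0.0:
        raise ValueError("constant residuals: Shapiro-Wilk undefined")
    w, p = scipy.stats.shapiro(r)
    (osm, osr), _ = scipy.stats.probplot(r, dist="norm")
    return NormalityResult(
        shapiro_w=float(w), shapiro_p=float(p), residuals=r,
        qq_theoretical=osm, qq_sample=osr,
    )


def cv_comparison_table(
    direct: DirectEstimates,
    hb: pd.DataFrame,
    per_area_gain: bool = False,
) -> pd.DataFrame:
    """Six-row CV summary (min, Q1, median, mean, Q3, max) with gains.

    The efficiency-gain column is ``100 (direct - HB) / direct`` applied
    row-wise to the summary cells (matching how such tables are usually
    assembled); ``per_area_gain=True`` instead summarises the per-area
    gains themselves.  Quantiles use linear interpolation between order
    statistics.
    """
    sampled = hb["sampled"].to_numpy(dtype=bool)
    d_cv = direct.cv
    h_cv = hb.loc[sampled, "hb_cv"].to_numpy(dtype=float)
    if d_cv.size == 0 or h_cv.size == 0:
        raise ValueError("no sampled areas with both CVs defined")
    if d_cv.shape != h_cv.shape:
        raise ValueError("direct and HB CV vectors must align")

    def six(v: np.ndarray) -> np.ndarray:
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        return np.array([v.min(), q1, med, v.mean(), q3, v.max()])

    d6, h6 = six(d_cv), six(h_cv)
    if per_area_gain:
        gain = six(100.0 * (d_cv - h_cv) / d_cv)
    else:
        gain = 100.0 * (d6 - h6) / d6
    return pd.DataFrame(
        {"quantity": list(CV_ROWS), "direct_cv": d6, "hb_cv": h6,
         "efficiency_gain": gain}
    )


def export_map_table(estimates: pd.DataFrame, path=None) -> pd.DataFrame:
    """Area-keyed table of HB means and CIs, joinable to a boundary file.

    One row per area, sampled and non-sampled alike.  Writes CSV when
    ``path`` is given; returns the table either way.
    """
    if estimates.empty:
        raise ValueError("no estimates to export")
    ids = estimates["area_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(
            f"duplicate area ids: {ids[ids.duplicated()].tolist()}"
        )
    if (ids == "").any():
        raise ValueError("empty area_id")
    out = estimates[
        ["area_id", "hb_mean", "ci_low", "ci_high", "sampled"]
    ].reset_index(drop=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out
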