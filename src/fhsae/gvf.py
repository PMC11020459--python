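"""Generalized variance function: smoothing noisy design variances.

Design variances of small-domain proportions are themselves unstable.
The GVF replaces them with fitted values from the log-log regression

    log(psi_i) = b0 + b1 * log(p_i) + e_i,   e_i ~ N(0, s2)

back-transformed with the smearing factor exp(s2_hat / 2) that corrects
the retransformation bias of exponentiating a log-scale prediction:

    smoothed_i = exp(s2_hat / 2) * exp(b0_hat + b1_hat * log p_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .direct import DirectEstimates


@dataclass
class GVFFit:
    beta0: float
    beta1: float
    sigma2_hat: float
    residuals: np.ndarray
    smoothed_var: np.ndarray  # aligned with the sampled areas of the input

    def predict(self, p: np.ndarray) -> np.ndarray:
        """Smoothed variance at proportion(s) ``p`` (must be in (0, 1))."""
        p = np.asarray(p, dtype=float)
        return np.exp(self.sigma2_hat / 2.0) * np.exp(
            self.beta0 + self.beta1 * np.log(p)
        )


def fit_gvf(direct: DirectEstimates) -> GVFFit:
    """OLS of log design variance on log proportion over sampled areas.

    Requires at least 3 sampled areas with proportions strictly inside
    (0, 1) and positive variances; the residual variance uses the
    unbiased n - 2 divisor.
    """
    p = direct.p
    psi = direct.psi
    usable = (p > 0.0) & (p < 1.0) & (psi > 0.0)
    if usable.sum() < 3:
        raise ValueError(
            f"GVF needs >= 3 sampled areas with p in (0,1) and psi > 0; "
            f"got {int(usable.sum())}"
        )
    x = np.log(p[usable])
    yv = np.log(psi[usable])
    if np.ptp(x) == 0.0:
        raise ValueError("zero spread in log(p): GVF slope unidentifiable")

    res = sm.OLS(yv, sm.add_constant(x)).fit()
    beta0, beta1 = res.params
    sigma2_hat = float(res.ssr / res.df_resid)

    fit = GVFFit(
        beta0=float(beta0),
        beta1=float(beta1),
        sigma2_hat=sigma2_hat,
        residuals=np.asarray(res.resid),
        smoothed_var=np.empty(0),
    )
    fit.smoothed_var = fit.predict(p)
    return fit


def select_variance(
    direct: DirectEstimates, gvf: GVFFit | None = None, mode: str = "gvf"
) -> np.ndarray:
    """Variance vector for the FH sampling model, over sampled areas.

    ``mode="raw"`` passes the design variances through; ``mode="gvf"``
    returns the smoothed variances (requires a fit).  The result is
    strictly positive either way.
    """
    if mode == "raw":
        psi = direct.psi
    elif mode == "gvf":
        if gvf is None:
            raise ValueError("mode='gvf' requires a GVFFit")
        psi = gvf.smoothed_var
    else:
        raise ValueError(f"mode must be 'raw' or 'gvf', got {mode!r}")
    if np.any(~np.isfinite(psi)) or np.any(psi <= 0.0):
        raise ValueError("variance vector must be finite and strictly positive")
    return np.asarray(psi, dtype=float)
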