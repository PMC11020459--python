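"""End-to-end pipeline: direct -> GVF -> HB fit -> predict -> diagnose.

A :class:`RunConfig` fully determines a run; two runs with identical
config and input produce byte-identical numeric outputs.  All tables are
CSV with fixed column order and 6-significant-digit formatting; scalar
reports are JSON.  Every artifact directory carries a run log with the
config hash, seed, stage timings and MCMC acceptance summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .areas import AreaTable, read_area_table
from .diagnostics import (
    bias_diagnostic,
    cv_comparison_table,
    export_map_table,
    predict_nonsampled,
    residual_normality,
    summarize_sampled,
)
from .direct import DirectEstimates, compute_direct
from .gvf import fit_gvf, select_variance
from .hb import (
    FHData,
    MCMCConfig,
    PriorSpec,
    compare_links,
    compute_dic,
    run_mcmc,
    summarize_coefficients,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    input: str = ""
    out: str = "fhsae_run"
    link: str = "logit"            # identity | log | logit | all
    variance_mode: str = "gvf"     # gvf | raw
    correction: str = "add-half"
    sigma2_upper: float = 1.0
    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 1
    n_chains: int = 2
    seed: int = 0
    proposal_sd: float = 0.5

    def validate(self) -> None:
        if self.link not in ("identity", "log", "logit", "all"):
            raise ValueError(f"link must be identity/log/logit/all, got {self.link!r}")
        if self.variance_mode not in ("gvf", "raw"):
            raise ValueError(f"variance_mode must be gvf/raw, got {self.variance_mode!r}")

    def mcmc(self) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
            n_chains=self.n_chains, seed=self.seed,
            proposal_sd=self.proposal_sd,
        )

    def prior(self) -> PriorSpec:
        return PriorSpec(sigma2_upper=self.sigma2_upper)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def make_fh_data(
    table: AreaTable, direct: DirectEstimates, psi: np.ndarray
) -> FHData:
    """Assemble sampled-area model inputs from the table and estimates."""
    sampled = table.sampled
    return FHData(
        p_direct=direct.p,
        psi=psi,
        X=table.design_matrix("sampled"),
        area_ids=table.area_ids[sampled],
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _max_split_rhat(samples) -> float | None:
    """Largest Gelman-Rubin statistic over beta, each chain split in two."""
    halves = []
    for chain in range(samples.n_chains):
        draws = samples.beta[samples.chain_id == chain]
        mid = len(draws) // 2
        if mid < 2:
            return None
        halves += [draws[:mid], draws[mid:2 * mid]]
    arr = np.stack(halves)                      # chains x draws x k
    n = arr.shape[1]
    cmeans = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean(axis=0)
    b = n * cmeans.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w).max())


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, table: AreaTable | None = None) -> Path:
    """Execute the full analysis and write artifacts under ``config.out``.

    Returns the artifact directory.  Any stage error aborts with the
    stage name; an ``INCOMPLETE`` marker flags partial output.
    """
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "INCOMPLETE").write_text("run in progress\n")

    log_lines: list[str] = [
        f"config_hash: {config.hash()}",
        f"seed: {config.seed}",
    ]
    t_all = time.perf_counter()

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            log_lines.append(f"stage {name}: FAILED ({exc})")
            (out / "run.log").write_text("\n".join(log_lines) + "\n")
            raise StageError(name, exc) from exc
        log_lines.append(f"stage {name}: {time.perf_counter() - t0:.2f}s")
        return result

    if table is None:
        table = stage("read", lambda: read_area_table(config.input))
    config.to_yaml(out / "config.yaml")

    direct = stage("direct", lambda: compute_direct(table, config.correction))
    _write_csv(direct.table, out / "direct_estimates.csv")

    gvf = stage("gvf", lambda: fit_gvf(direct))
    with open(out / "gvf_fit.json", "w") as fh:
        json.dump(
            {"beta0": gvf.beta0, "beta1": gvf.beta1,
             "sigma2_hat": gvf.sigma2_hat}, fh, indent=2,
        )
    paired = pd.DataFrame(
        {
            "area_id": table.area_ids[table.sampled],
            "raw_var": direct.psi,
            "smoothed_var": gvf.smoothed_var,
        }
    )
    _write_csv(paired, out / "variance_comparison.csv")

    psi = stage("variance", lambda: select_variance(direct, gvf, config.variance_mode))
    data = make_fh_data(table, direct, psi)
    coef_names = ["const"] + table.covariate_names
    prior, mcmc = config.prior(), config.mcmc()

    links = ("identity", "log", "logit") if config.link == "all" else (config.link,)
    if len(links) > 1:
        dic_table = stage(
            "compare-links",
            lambda: compare_links(data, prior, mcmc, links=links),
        )
        _write_csv(dic_table.drop(columns=[], errors="ignore"), out / "dic_comparison.csv")
        fits = dic_table.attrs["fits"]
        best = dic_table.loc[dic_table["best"], "link"].iloc[0]
        samples = fits[best]
        samples.coef_names = coef_names
        log_lines.append(f"selected link by DIC: {best}")
    else:
        samples = stage(
            "fit",
            lambda: run_mcmc(data, links[0], prior, mcmc, coef_names=coef_names),
        )
        dic = compute_dic(samples, data)
        _write_csv(
            pd.DataFrame(
                [{"link": links[0], "dic": dic.dic, "dbar": dic.dbar,
                  "dhat": dic.dhat, "pd": dic.pd, "estimable": True,
                  "best": True}]
            ),
            out / "dic_comparison.csv",
        )
    log_lines.append(
        "acceptance rate: min %.3f mean %.3f max %.3f"
        % (samples.accept_rate.min(), samples.accept_rate.mean(),
           samples.accept_rate.max())
    )
    rhat = _max_split_rhat(samples)
    if rhat is not None:
        log_lines.append(f"max split-chain rhat (beta): {rhat:.4f}")

    _write_csv(samples.to_frame(), out / "posterior_draws.csv")
    _write_csv(summarize_coefficients(samples), out / "coefficients.csv")

    est_s = stage(
        "summarize",
        lambda: summarize_sampled(samples, table.area_ids[table.sampled]),
    )
    estimates = est_s
    if (~table.sampled).any():
        est_ns = stage(
            "predict",
            lambda: predict_nonsampled(
                samples,
                table.design_matrix("nonsampled"),
                table.area_ids[~table.sampled],
                seed=config.seed + 1,
            ),
        )
        estimates = pd.concat([est_s, est_ns], ignore_index=True)
    _write_csv(estimates, out / "estimates.csv")
    export_map_table(estimates, out / "map_table.csv")

    def _diagnose():
        bias = bias_diagnostic(direct, est_s)
        norm = residual_normality(samples, data)
        cv_tab = cv_comparison_table(direct, est_s)
        return bias, norm, cv_tab

    bias, norm, cv_tab = stage("diagnose", _diagnose)
    _write_csv(cv_tab, out / "cv_comparison.csv")
    _write_csv(
        pd.DataFrame(
            {"theoretical": norm.qq_theoretical, "sample": norm.qq_sample}
        ),
        out / "qq_residuals.csv",
    )
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(
            {
                "bias_slope": bias.slope,
                "bias_intercept": bias.intercept,
                "shapiro_w": norm.shapiro_w,
                "shapiro_p": norm.shapiro_p,
                "sigma2_nu_posterior_mean": float(samples.sigma2.mean()),
            },
            fh,
            indent=2,
        )

    log_lines.append(f"total: {time.perf_counter() - t_all:.2f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "INCOMPLETE").unlink()
    return out
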