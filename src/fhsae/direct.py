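"""Design-based direct estimates per area: proportion, variance, CV.

For a sampled area the direct estimator is the sample proportion
``p_i = y_i / n_i`` with design variance ``psi_i = p_i (1 - p_i) / n_i``
and percent coefficient of variation ``cv_i = 100 sqrt(psi_i) / p_i``.

Boundary cells (``y in {0, n}``) would give zero variance and an
undefined log, so they are replaced by a continuity-corrected proportion
``(y + 0.5) / (n + 1)`` before variance and CV computation and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areas import AreaTable


@dataclass
class DirectEstimates:
    """Per-area direct estimates; non-sampled rows hold NaN.

    ``table`` has one row per area (input order) with columns
    area_id, sampled, p (corrected), p_raw, psi, cv, adjusted.
    """

    table: pd.DataFrame

    @property
    def sampled_mask(self) -> np.ndarray:
        return self.table["sampled"].to_numpy(dtype=bool)

    def sampled_values(self, col: str) -> np.ndarray:
        return self.table.loc[self.table["sampled"], col].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        """Corrected proportions of sampled areas, in table order."""
        return self.sampled_values("p")

    @property
    def psi(self) -> np.ndarray:
        return self.sampled_values("psi")

    @property
    def cv(self) -> np.ndarray:
        return self.sampled_values("cv")


def continuity_correct(y: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return corrected proportions and a flag marking corrected cells."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, y / n, np.nan)
    boundary = (n > 0) & ((y == 0) | (y == n))
    p = np.where(boundary, (y + 0.5) / (n + 1.0), p)
    return p, boundary


def compute_direct(table: AreaTable, correction: str = "add-half") -> DirectEstimates:
    """Direct proportion, design variance and percent CV per sampled area.

    Parameters
    ----------
    table : AreaTable
    correction : {"add-half", "none"}
        Boundary-cell rule.  "add-half" substitutes (y+0.5)/(n+1) for
        y in {0, n}; "none" leaves boundary cells untouched (their psi is
        then 0 and the GVF cannot be fitted on them).
    """
    if correction not in ("add-half", "none"):
        raise ValueError(f"unknown correction rule {correction!r}")
    df = table.df
    n = df["n"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    sampled = table.sampled
    if not sampled.any():
        raise ValueError("no sampled areas: every row has n = 0")

    with np.errstate(invalid="ignore", divide="ignore"):
        p_raw = np.where(sampled, y / np.where(sampled, n, 1.0), np.nan)
    if correction == "add-half":
        p_tilde, adjusted = continuity_correct(y, n)
    else:
        p_tilde, adjusted = p_raw.copy(), np.zeros(len(df), dtype=bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(sampled, p_tilde * (1.0 - p_tilde) / np.where(sampled, n, 1.0), np.nan)
        cv = np.where(sampled, 100.0 * np.sqrt(psi) / p_tilde, np.nan)

    out = pd.DataFrame(
        {
            "area_id": df["area_id"].to_numpy(),
            "sampled": sampled,
            "p": p_tilde,
            "p_raw": p_raw,
            "psi": psi,
            "cv": cv,
            "adjusted": adjusted,
        }
    )
    return DirectEstimates(out)
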