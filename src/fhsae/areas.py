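"""Area-level data container and its CSV schema.

One row per small area (administrative zone): sample size ``n``, success
count ``y``, population size ``N``, covariates ``x1..xp`` (an intercept
column is implicit).  Non-sampled areas carry ``n = 0`` and keep their
covariates so that synthetic prediction remains possible.

Optional columns ``p_true`` and ``nu_true`` hold simulation truth when the
table was produced by the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("area_id", "n", "y", "N")
TRUTH_COLUMNS = ("p_true", "nu_true")


class SchemaError(ValueError):
    """An area table violates the required schema."""


def _covariate_columns(columns) -> list[str]:
    cols = [c for c in columns if c.startswith("x") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


@dataclass
class AreaTable:
    """Validated area-level table.

    Attributes
    ----------
    df : pandas.DataFrame
        The underlying table, one row per area, in input order.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_area_frame(self.df)
        if "sampled" not in self.df.columns:
            self.df["sampled"] = self.df["n"] > 0

    # -- basic accessors -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.df)

    @property
    def covariate_names(self) -> list[str]:
        return _covariate_columns(self.df.columns)

    @property
    def p(self) -> int:
        """Number of covariates excluding the intercept."""
        return len(self.covariate_names)

    @property
    def sampled(self) -> np.ndarray:
        return self.df["sampled"].to_numpy(dtype=bool)

    @property
    def area_ids(self) -> np.ndarray:
        return self.df["area_id"].to_numpy()

    def design_matrix(self, which: str = "all") -> np.ndarray:
        """m x (p+1) design with a leading intercept column of ones.

        ``which`` selects "all", "sampled" or "nonsampled" rows.
        """
        X = np.column_stack(
            [np.ones(self.m)]
            + [self.df[c].to_numpy(dtype=float) for c in self.covariate_names]
        )
        if which == "all":
            return X
        if which == "sampled":
            return X[self.sampled]
        if which == "nonsampled":
            return X[~self.sampled]
        raise ValueError(f"which must be all/sampled/nonsampled, got {which!r}")

    def subset(self, mask: np.ndarray) -> "AreaTable":
        return AreaTable(self.df.loc[mask].copy())

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.drop(columns=["sampled"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AreaTable":
        return read_area_table(path)


def validate_area_frame(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` naming the offending column/row."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df["area_id"].duplicated().any():
        dupes = df.loc[df["area_id"].duplicated(), "area_id"].tolist()
        raise SchemaError(f"duplicate area_id values: {dupes}")
    if df["area_id"].isna().any() or (df["area_id"].astype(str) == "").any():
        raise SchemaError("empty area_id")
    for col in ("n", "y", "N"):
        vals = df[col]
        if vals.isna().any():
            raise SchemaError(f"column {col!r} contains missing values")
        if not np.allclose(vals, np.round(vals)):
            raise SchemaError(f"column {col!r} must be integer-valued")
    n = df["n"].to_numpy(dtype=int)
    y = df["y"].to_numpy(dtype=int)
    N = df["N"].to_numpy(dtype=int)
    for i in range(len(df)):
        if n[i] < 0:
            raise SchemaError(f"row {i}: n = {n[i]} < 0")
        if N[i] <= 0:
            raise SchemaError(f"row {i}: N = {N[i]} <= 0")
        if y[i] < 0 or y[i] > n[i]:
            raise SchemaError(f"row {i}: y = {y[i]} outside [0, n = {n[i]}]")
        if n[i] > N[i]:
            raise SchemaError(f"row {i}: n = {n[i]} > N = {N[i]}")
    for col in _covariate_columns(df.columns):
        if df[col].isna().any():
            raise SchemaError(f"covariate column {col!r} contains missing values")


def read_area_table(path) -> AreaTable:
    """Read and validate an area-level CSV (schema above)."""
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise SchemaError(f"{path}: not valid UTF-8 ({exc})") from exc
    if df.empty and df.columns.empty:
        raise SchemaError(f"{path}: missing header")
    df["area_id"] = df["area_id"].astype(str)
    return AreaTable(df)
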