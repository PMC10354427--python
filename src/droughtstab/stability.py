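"""Drought-stability index: per-environment min-max normalization and the CV.

A genotype's stability over E treatment-year combinations ("environments") is
summarised by the coefficient of variation of its fresh weight,

    CV_i = sigma_i / mu_i * 100,

computed after each environment's weights are min-max scaled to [0, 1] so that
environments with large means do not dominate. Low CV = stable under drought.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EnvironmentTable", "StabilityIndex", "minmax_normalize", "compute_cv"]


@dataclass
class EnvironmentTable:
    """Genotype x environment fresh-weight table (grams, non-negative, NaN allowed)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("need >=2 environments")
        if not self.values.index.is_unique:
            raise ValueError("genotype ids must be unique")

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def environment_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="genotype").melt(
            id_vars="genotype", var_name="environment", value_name="value"
        )
        return long.dropna(subset=["value"]).reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "EnvironmentTable":
        wide = long.pivot_table(index="genotype", columns="environment", values="value", aggfunc="mean")
        return cls(values=wide)


@dataclass
class StabilityIndex:
    """Per-genotype CV (percent) with the mean and sample SD it came from."""

    cv: pd.Series
    mu: pd.Series
    sigma: pd.Series


def minmax_normalize(table: EnvironmentTable) -> EnvironmentTable:
    """Scale each environment column to [0, 1]: (x - min) / (max - min)."""
    vals = table.values
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    degenerate = span[span <= 0].index.tolist()
    if degenerate:
        raise ValueError(f"constant environment column(s): {degenerate}")
    return EnvironmentTable(values=(vals - lo) / span)


def compute_cv(normalized: EnvironmentTable, eps: float = 1e-6) -> StabilityIndex:
    """CV_i = sigma_i / mu_i * 100 over environments, missing cells excluded.

    sigma uses the sample (n-1) denominator. Genotypes whose normalized mean
    is below ``eps`` get a missing CV (the ratio is undefined near mu = 0) and
    a warning; genotypes with fewer than 2 observed environments likewise.
    """
    vals = normalized.values
    n_obs = vals.notna().sum(axis=1)
    mu = vals.mean(axis=1)
    sigma = vals.std(axis=1, ddof=1)
    cv = sigma / mu * 100.0
    bad_mu = (mu <= eps) & (n_obs >= 2)
    if bad_mu.any():
        warnings.warn(
            f"{int(bad_mu.sum())} genotype(s) with normalized mean <= {eps}: CV set missing",
            stacklevel=2,
        )
    cv[bad_mu | (n_obs < 2)] = np.nan
    cv.name, mu.name, sigma.name = "cv", "mu", "sigma"
    return StabilityIndex(cv=cv, mu=mu, sigma=sigma)
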