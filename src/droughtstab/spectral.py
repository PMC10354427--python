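"""Vegetation-index computation and NDVI-threshold plant segmentation.

Plots are imaged with a multispectral camera; each plot yields a stack of
per-band reflectance arrays. A vegetation index (VI) is computed pixel-wise,
plant pixels are segmented by thresholding NDVI, and the median VI over the
segmented pixels is the plot's representative value for that date. Collected
over dates, those medians form a genotype x timepoint trait table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReflectanceStack",
    "TimeSeriesTrait",
    "compute_vi",
    "segment_plants",
    "plot_representative",
    "read_reflectance_csv",
]

#: bands required by each supported vegetation index
VI_BANDS = {
    "NDVI": ("nir", "red"),
    "NDRE": ("nir", "red_edge"),
}


@dataclass
class ReflectanceStack:
    """Per-plot reflectance arrays keyed by band name.

    Bands are 2-D arrays of reflectance (unitless ratios against a calibration
    panel, typically in [0, ~1.5]); all bands must share one shape.
    """

    bands: dict[str, np.ndarray]
    plot_id: str = ""

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(b).shape for name, b in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"bands have inconsistent shapes: {shapes}")
        for name, b in self.bands.items():
            arr = np.asarray(b, dtype=float)
            if np.nanmin(arr) < 0:
                raise ValueError(f"band {name!r} contains negative reflectance")
            self.bands[name] = arr


@dataclass
class TimeSeriesTrait:
    """Genotype x timepoint table of plot-representative VI values.

    ``values`` is indexed by genotype id with one column per measurement date;
    ``timepoints`` are days after sowing (DAS), strictly increasing. Missing
    entries (rained-out flights, dropped plots) are allowed.
    """

    values: pd.DataFrame
    timepoints: np.ndarray
    treatment: str = ""
    year: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.timepoints.ndim != 1 or len(self.timepoints) != self.values.shape[1]:
            raise ValueError("timepoints must be 1-D with one entry per column")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.values.notna().sum(axis=1).min() < 1:
            raise ValueError("each genotype needs at least one non-missing value")

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.values.index)

    def to_long(self) -> pd.DataFrame:
        """Long form (genotype, treatment, year, das, value) shared across the pipeline."""
        long = self.values.copy()
        long.columns = self.timepoints
        long = long.reset_index(names="genotype").melt(
            id_vars="genotype", var_name="das", value_name="value"
        )
        long.insert(1, "treatment", self.treatment)
        long.insert(2, "year", self.year)
        return long.dropna(subset=["value"]).reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, treatment: str | None = None, year: str | None = None) -> "TimeSeriesTrait":
        df = long.copy()
        if treatment is not None:
            df = df[df["treatment"].astype(str) == str(treatment)]
        if year is not None:
            df = df[df["year"].astype(str) == str(year)]
        if df.empty:
            raise ValueError("no records for requested treatment/year")
        wide = df.pivot_table(index="genotype", columns="das", values="value", aggfunc="mean")
        wide = wide.sort_index(axis=1)
        return cls(
            values=wide,
            timepoints=np.asarray(wide.columns, dtype=float),
            treatment=str(df["treatment"].iloc[0]) if "treatment" in df else "",
            year=str(df["year"].iloc[0]) if "year" in df else "",
        )


def compute_vi(stack: ReflectanceStack, index: str = "NDVI") -> np.ndarray:
    """Compute a normalized-difference vegetation index pixel-wise.

    NDVI = (nir - red) / (nir + red); NDRE = (nir - red_edge) / (nir + red_edge).
    Pixels where the denominator is zero become NaN.
    """
    index = index.upper()
    if index not in VI_BANDS:
        raise ValueError(f"unknown index {index!r}; supported: {sorted(VI_BANDS)}")
    names = VI_BANDS[index]
    for name in names:
        if name not in stack.bands:
            raise ValueError(f"band {name!r} required for {index} is missing")
    a, b = (stack.bands[n] for n in names)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        vi = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0), np.nan)
    return vi


def segment_plants(ndvi: np.ndarray, threshold: float = 0.15) -> np.ndarray:
    """Boolean plant mask: NDVI strictly greater than ``threshold``; NaN pixels are False."""
    ndvi = np.asarray(ndvi, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(ndvi, nan=-np.inf) > threshold


def plot_representative(vi: np.ndarray, mask: np.ndarray) -> float:
    """Median VI over masked plant pixels (NaN with a warning if the mask is empty).

    The median damps residual background pixels that survive segmentation; for
    an even count it is the mean of the two central order statistics.
    """
    vi = np.asarray(vi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = vi[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        warnings.warn("empty plant mask: plot dropped (missing value)", stacklevel=2)
        return float("nan")
    return float(np.median(vals))


def read_reflectance_csv(directory: str | Path, plot_id: str = "") -> ReflectanceStack:
    """Read one plot's bands from ``<directory>/<band>.csv`` plain 2-D arrays."""
    directory = Path(directory)
    bands: dict[str, np.ndarray] = {}
    for path in sorted(directory.glob("*.csv")):
        bands[path.stem] = np.loadtxt(path, delimiter=",", ndmin=2)
    if not bands:
        raise FileNotFoundError(f"no band CSVs found under {directory}")
    return ReflectanceStack(bands=bands, plot_id=plot_id or directory.name)
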