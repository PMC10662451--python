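"""Temporal harmonization of flux estimates covering different periods.

Inventories and earth-observation products rarely cover the same years. Two
operations make their averages comparable: fractional rescaling of a
short-period average against a reference annual series, and last-year
extension of a series that stops short of the target year. Means are
arithmetic over calendar years, inclusive of both period endpoints; net flux
is always recomputed from rescaled gross components, never rescaled itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedRatioError

__all__ = ["AnnualSeries", "fractional_rescale", "extend_last_year"]


@dataclass
class AnnualSeries:
    """A contiguous year-indexed flux series (unit carried as metadata)."""

    values: pd.Series
    unit: str = "Mg CO2e/yr"

    def __post_init__(self):
        if len(self.values) == 0:
            raise DataError("annual series must contain at least one year")
        years = self.values.index.to_numpy(dtype=np.int64)
        self.values = pd.Series(
            self.values.to_numpy(dtype=np.float64), index=years, name="value"
        )
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise DataError("annual series years must be contiguous")

    @property
    def start(self) -> int:
        return int(self.values.index[0])

    @property
    def end(self) -> int:
        return int(self.values.index[-1])

    def mean_over(self, period: tuple[int, int]) -> float:
        start, end = period
        if end < start:
            raise DataError(f"malformed period {period}")
        if start < self.start or end > self.end:
            raise DataError(
                f"period {period} not covered by series [{self.start}, {self.end}]"
            )
        return float(self.values.loc[start:end].mean())

    @classmethod
    def from_mapping(cls, mapping, unit: str = "Mg CO2e/yr") -> "AnnualSeries":
        series = pd.Series(dict(sorted(mapping.items())))
        return cls(values=series, unit=unit)

    @classmethod
    def from_csv(cls, path, unit: str = "Mg CO2e/yr") -> "AnnualSeries":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(values=pd.Series(df["value"].values, index=df["year"].values), unit=unit)

    def to_csv(self, path) -> None:
        pd.DataFrame({"year": self.values.index, "value": self.values.values}).to_csv(
            path, index=False, float_format="%.17g"
        )


def fractional_rescale(
    x_short: float,
    ref: AnnualSeries,
    short_period: tuple[int, int],
    target_period: tuple[int, int],
) -> float:
    """Rescale a short-period average flux to a target period.

    Multiplies ``x_short`` by the ratio of the reference series' mean over the
    target period to its mean over the short period. Applied independently to
    gross emissions and gross removals, per region.
    """
    short_mean = ref.mean_over(short_period)
    target_mean = ref.mean_over(target_period)
    if short_mean == 0:
        raise UndefinedRatioError("reference mean over the short period is zero")
    return x_short * target_mean / short_mean


def extend_last_year(series: AnnualSeries, to_year: int) -> AnnualSeries:
    """Extend a series by repeating its final value through ``to_year``."""
    if to_year < series.start:
        raise DataError(f"to_year {to_year} precedes series start {series.start}")
    if to_year <= series.end:
        return AnnualSeries(values=series.values.copy(), unit=series.unit)
    years = np.arange(series.start, to_year + 1)
    vals = np.concatenate(
        [
            series.values.to_numpy(),
            np.full(to_year - series.end, series.values.iloc[-1]),
        ]
    )
    return AnnualSeries(values=pd.Series(vals, index=years), unit=series.unit)
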