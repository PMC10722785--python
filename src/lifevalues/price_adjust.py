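"""Price-year adjustment of stated values onto the 2019/2020 base year.

The shipped index series are back-derived from published stated/adjusted
value pairs (one implied level per country-year, base year = 1.0), so no
external deflator download is involved. Whether a value is adjusted at all
is an editorial flag on the registry record (``needs_update``), not an
inference: many pre-base-year values were left nominal by their sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._money import MoneyRange
from .registry import CountryParams

__all__ = ["PriceIndexSeries", "PriceYearError", "adjust", "series_for"]


class PriceYearError(KeyError):
    """A year needed for adjustment is missing from the index series."""


@dataclass(frozen=True)
class PriceIndexSeries:
    country: str
    levels: Mapping[int, float]  # year -> positive index level, base arbitrary
    base_year: int

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.levels.values()):
            raise ValueError(f"{self.country}: index levels must be positive")

    def level(self, year: int) -> float:
        try:
            return self.levels[year]
        except KeyError:
            raise PriceYearError(
                f"{self.country} price index has no level for year {year}"
            ) from None

    def factor(self, from_year: int) -> float:
        """Multiplicative uplift from ``from_year`` prices to base-year prices."""
        return self.level(self.base_year) / self.level(from_year)


def series_for(params: CountryParams) -> PriceIndexSeries:
    return PriceIndexSeries(params.country, dict(params.price_index), params.base_year)


def adjust(
    value: MoneyRange,
    from_year: int,
    series: PriceIndexSeries,
    needs_update: bool,
) -> MoneyRange:
    """Express ``value`` in base-year prices, rounded to whole currency units.

    When ``needs_update`` is false the value passes through unchanged
    (sources frequently leave older values nominal on purpose).
    """
    if not needs_update:
        return value
    f = series.factor(from_year)
    return value.map(lambda v: v * f).rounded()
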