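"""Robustness scans over the conversion assumptions.

The headline comparison rests on two mapped parameters: the remaining life
expectancy entering the VSL/VOLY annuity (equivalently, the reference age)
and the VOLY:QALY ratio rho (bounded above by 1:1, since a life year cannot
be worth more than a full-health QALY). The scan re-runs the whole
adjust-convert-compare pipeline on a grid of (age, rho) cells and reports
the three headline counts per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .comparison import ComparisonRow, ConvertedEstimate, build_comparison, counts_summary
from .conversion import convert, rescaled_annuity
from .price_adjust import adjust, series_for
from .registry import CountryParams, VoLEstimate

__all__ = ["SensitivityGrid", "SensitivityCell", "SensitivityResult", "run_sensitivity"]

BASELINE_AGE = 40.0


@dataclass(frozen=True)
class SensitivityGrid:
    """Grid of reference ages and VOLY:QALY ratios to scan."""

    ages: Sequence[float] = (20.0, 30.0, 40.0, 50.0, 60.0)
    rhos: Sequence[float] = (0.91996, 0.95, 1.0)

    def __post_init__(self) -> None:
        if any(not (0 < r <= 1) for r in self.rhos):
            raise ValueError("rho values must lie in (0, 1] (1:1 upper bound)")
        if any(a < 0 for a in self.ages):
            raise ValueError("ages must be non-negative")


@dataclass(frozen=True)
class SensitivityCell:
    age: float
    rho: float
    below_100_overall: int
    below_50_transport: int
    below_50_environment: int
    comparisons: int
    annuity_rescaled: bool  # True when any country used the fallback rescaling


@dataclass
class SensitivityResult:
    cells: list[SensitivityCell]
    majority_threshold: int
    baseline: tuple[float, float]

    @property
    def robust(self) -> bool:
        """Whether health is valued lower in a majority of comparisons in every cell."""
        return all(c.below_100_overall >= self.majority_threshold for c in self.cells)

    def cell(self, age: float, rho: float) -> SensitivityCell:
        for c in self.cells:
            if c.age == age and c.rho == rho:
                return c
        raise KeyError((age, rho))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "age": c.age,
            "rho": c.rho,
            "comparisons": c.comparisons,
            "below_100_overall": c.below_100_overall,
            "below_50_transport": c.below_50_transport,
            "below_50_environment": c.below_50_environment,
            "annuity_rescaled": c.annuity_rescaled,
        } for c in self.cells])


def _cell_params(
    params: Mapping[str, CountryParams], age: float, rho: float
) -> tuple[dict[str, CountryParams], bool]:
    """Per-country parameters for one grid cell.

    The annuity factor is rebuilt from (r, LE) where known, otherwise
    rescaled from the derived factor (flagged). When the cell's rho equals a
    country's configured ratio the configured reciprocal is kept, so the
    baseline cell is bit-identical to a direct pipeline run; any other rho
    uses the exact reciprocal 1/rho.
    """
    out = {}
    any_rescaled = False
    for code, p in params.items():
        a = rescaled_annuity(p, age)
        rescaled = p.annuity_override is not None and age != (
            p.reference_age if p.reference_age is not None else BASELINE_AGE
        )
        any_rescaled = any_rescaled or rescaled
        recip = p.rho_reciprocal if rho == p.rho else 1.0 / rho
        out[code] = replace(
            p,
            rho=rho,
            rho_reciprocal=recip,
            annuity_override=a,
            # the override now embodies the cell's age; drop (LE, age) so the
            # closed form cannot silently disagree with it
            life_expectancy=None,
            reference_age=None,
        )
    return out, any_rescaled


def run_sensitivity(
    records: Sequence[VoLEstimate],
    params: Mapping[str, CountryParams],
    grid: SensitivityGrid = SensitivityGrid(),
    majority_threshold: int = 8,
) -> SensitivityResult:
    """Re-run adjust → convert → compare for every (age, rho) cell.

    ``majority_threshold`` is the minimum below-100 count for a cell to
    support the qualitative conclusion (default: a strict majority of the
    15 shipped comparisons).
    """
    for p in params.values():
        if p.life_expectancy is not None:
            for age in grid.ages:
                if age >= p.life_expectancy:
                    raise ValueError(
                        f"age {age} is at or beyond {p.country} life expectancy"
                        f" {p.life_expectancy}")
    cells = []
    for age in grid.ages:
        for rho in grid.rhos:
            cell_params, rescaled = _cell_params(params, age, rho)
            rows = _compare(records, cell_params)
            s = counts_summary(rows)
            cells.append(SensitivityCell(
                age=age,
                rho=rho,
                below_100_overall=s["below_100_overall"],
                below_50_transport=s["below_50_transport"],
                below_50_environment=s["below_50_environment"],
                comparisons=s["comparisons"],
                annuity_rescaled=rescaled,
            ))
    return SensitivityResult(cells, majority_threshold, (BASELINE_AGE, 0.91996))


def _compare(
    records: Sequence[VoLEstimate], params: Mapping[str, CountryParams]
) -> list[ComparisonRow]:
    converted = []
    for r in records:
        p = params[r.country]
        adjusted = adjust(r.stated, r.stated_year, series_for(p), r.needs_update)
        converted.append(ConvertedEstimate(r.with_adjusted(adjusted),
                                           convert(adjusted, r.measure, p)))
    return build_comparison(converted)
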