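"""Cross-sector comparison: health benchmarks as a percentage of the value
of a QALY implied by transport and environment benchmarks.

All comparisons are within-country ratios of VOQs in local currency, so no
exchange-rate or purchasing-power handling is ever needed. A non-health
benchmark whose stated value was a range contributes one comparison per
endpoint; a health reference range keeps one row with a percentage range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence, Union
from pathlib import Path

import pandas as pd

from ._money import MoneyRange, round_half_away
from .conversion import ConversionTriple
from .registry import Sector, VoLEstimate

__all__ = [
    "ConvertedEstimate",
    "ComparisonRow",
    "health_share",
    "build_comparison",
    "count_below",
    "counts_summary",
    "health_baseline_index",
    "comparison_to_frame",
    "comparison_to_markdown",
    "write_comparison",
]


class ConvertedEstimate(NamedTuple):
    record: VoLEstimate
    triple: ConversionTriple


@dataclass(frozen=True)
class ComparisonRow:
    """One health-vs-other-sector comparison."""

    country: str
    other_sector: Sector
    other_source: str
    health_source: str
    health_voq: MoneyRange
    other_voq: float
    health_pct: tuple[int, int]  # integer percent range, lower <= upper


def health_share(health_voq: MoneyRange, other_voq: float) -> tuple[int, int]:
    """Health VOQ as a percentage of the other sector's VOQ, per endpoint.

    Rounded to the nearest integer percent, half away from zero.
    """
    if health_voq.lower <= 0 or other_voq <= 0:
        raise ValueError("VOQ values must be strictly positive")
    return (
        round_half_away(100.0 * health_voq.lower / other_voq),
        round_half_away(100.0 * health_voq.upper / other_voq),
    )


def _health_reference(
    country: str, converted: Sequence[ConvertedEstimate]
) -> tuple[MoneyRange, str]:
    refs = [ce for ce in converted
            if ce.record.country == country and ce.record.is_hta_reference]
    if not refs:
        raise ValueError(f"{country}: no health reference benchmark flagged")
    lower = min(ce.triple.voq.lower for ce in refs)
    upper = max(ce.triple.voq.upper for ce in refs)
    if any(ce.record.hta_ref_bound == "lower" for ce in refs):
        rng = MoneyRange.point(lower)
    else:
        rng = MoneyRange(lower, upper)
    source = "/".join(dict.fromkeys(ce.record.source for ce in refs))
    return rng, source


def build_comparison(converted: Sequence[ConvertedEstimate]) -> list[ComparisonRow]:
    """Build the cross-sector comparison rows from flagged conversions.

    Rows are grouped by country in first-appearance order, transport before
    environment, preserving source-table order within a sector.
    """
    countries = list(dict.fromkeys(ce.record.country for ce in converted
                                   if ce.record.in_comparison_set))
    rows: list[ComparisonRow] = []
    for country in countries:
        health_voq, health_source = _health_reference(country, converted)
        for sector in (Sector.TRANSPORT, Sector.ENVIRONMENT):
            for ce in converted:
                r = ce.record
                if r.country != country or not r.in_comparison_set or r.sector is not sector:
                    continue
                for endpoint in ce.triple.voq.endpoints():
                    rows.append(ComparisonRow(
                        country=country,
                        other_sector=sector,
                        other_source=r.source,
                        health_source=health_source,
                        health_voq=health_voq,
                        other_voq=endpoint,
                        health_pct=health_share(health_voq, endpoint),
                    ))
    return rows


def count_below(
    rows: Iterable[ComparisonRow],
    cutoff: int,
    sector: Optional[Sector] = None,
) -> int:
    """Comparisons whose *upper* health percentage is strictly below ``cutoff``.

    The upper endpoint is the operative one: a comparison only counts as
    "health valued lower" if even the most generous health benchmark falls
    below the other sector's value.
    """
    return sum(
        1 for r in rows
        if (sector is None or r.other_sector is sector) and r.health_pct[1] < cutoff
    )


def counts_summary(rows: Sequence[ComparisonRow]) -> dict[str, int]:
    return {
        "comparisons": len(rows),
        "below_100_overall": count_below(rows, 100),
        "transport_comparisons": sum(1 for r in rows if r.other_sector is Sector.TRANSPORT),
        "below_50_transport": count_below(rows, 50, Sector.TRANSPORT),
        "environment_comparisons": sum(1 for r in rows if r.other_sector is Sector.ENVIRONMENT),
        "below_50_environment": count_below(rows, 50, Sector.ENVIRONMENT),
    }


@dataclass(frozen=True)
class IndexEntry:
    """Other-sector value indexed against the country's health benchmark = 100."""

    country: str
    sector: Sector
    source: str
    index: tuple[float, float]  # (vs upper health value, vs lower health value)


def health_baseline_index(rows: Sequence[ComparisonRow]) -> list[IndexEntry]:
    """Per comparison, 100 * other_voq / health_voq (range-aware); health = 100."""
    out = []
    for r in rows:
        out.append(IndexEntry(
            country=r.country,
            sector=r.other_sector,
            source=r.other_source,
            index=(
                100.0 * r.other_voq / r.health_voq.upper,
                100.0 * r.other_voq / r.health_voq.lower,
            ),
        ))
    return out


def _pct_str(pct: tuple[int, int]) -> str:
    return f"{pct[0]}%" if pct[0] == pct[1] else f"{pct[0]}–{pct[1]}%"


def comparison_to_frame(rows: Sequence[ComparisonRow], human: bool = False) -> pd.DataFrame:
    """Comparison rows as a DataFrame in the published column order.

    ``human=False`` keeps machine-friendly plain numbers; ``human=True``
    formats currency with thousands separators and percentages as ranges.
    """
    data = []
    for r in rows:
        if human:
            data.append({
                "country": r.country,
                "health_source": r.health_source,
                "health_value": str(r.health_voq),
                "sector": r.other_sector.value,
                "source": r.other_source,
                "value": f"{r.other_voq:,.0f}",
                "health_as_pct": _pct_str(r.health_pct),
            })
        else:
            data.append({
                "country": r.country,
                "health_source": r.health_source,
                "health_voq_lower": r.health_voq.lower,
                "health_voq_upper": r.health_voq.upper,
                "sector": r.other_sector.value,
                "source": r.other_source,
                "value": r.other_voq,
                "health_pct_lower": r.health_pct[0],
                "health_pct_upper": r.health_pct[1],
            })
    return pd.DataFrame(data)


def comparison_to_markdown(rows: Sequence[ComparisonRow]) -> str:
    return comparison_to_frame(rows, human=True).to_markdown(index=False)


def write_comparison(rows: Sequence[ComparisonRow], out_dir: Union[str, Path]) -> None:
    out = Path(out_dir)
    comparison_to_frame(rows).to_csv(out / "comparison.csv", index=False)
    (out / "comparison.md").write_text(comparison_to_markdown(rows) + "\n", encoding="utf-8")
    with open(out / "counts.json", "w", encoding="utf-8") as fh:
        json.dump(counts_summary(rows), fh, indent=2)
        fh.write("\n")
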