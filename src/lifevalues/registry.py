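"""Domain types and I/O for the registry of published value-of-life benchmarks.

The packaged fixture transcribes the benchmark tables for the six study
countries (UK, NL, CA, JP, AU, NZ): one row per published estimate, with the
flags that control price-year adjustment and membership in the cross-sector
comparison. Country-level conversion parameters (discount rate, life
expectancy, VOLY:QALY ratio, price-index series) live in a YAML config.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
import yaml

from ._money import MoneyRange

__all__ = [
    "Sector",
    "Measure",
    "VoLEstimate",
    "CountryParams",
    "Finding",
    "ValidationReport",
    "RegistryError",
    "load_registry",
    "write_registry",
    "validate_registry",
    "load_params",
    "save_params",
    "default_registry",
    "default_params",
]


class RegistryError(ValueError):
    """Malformed or inconsistent registry input."""


class Sector(str, enum.Enum):
    HEALTH = "health"
    TRANSPORT = "transport"
    ENVIRONMENT = "environment"
    OTHER = "other"


class Measure(str, enum.Enum):
    """Measure of the value of life, normalised across published synonyms.

    VPF (value of a prevented fatality) is the same quantity as VSL; SLY
    (statistical life year) the same as VOLY; a bare "QALY" amount is a VOQ.
    """

    VSL = "VSL"
    VOLY = "VOLY"
    VOQ = "VOQ"

    @classmethod
    def parse(cls, token: str) -> "Measure":
        aliases = {"VPF": cls.VSL, "SLY": cls.VOLY, "QALY": cls.VOQ}
        t = token.strip().upper()
        if t in aliases:
            return aliases[t]
        try:
            return cls(t)
        except ValueError:
            raise RegistryError(f"unknown measure token {token!r}") from None


@dataclass(frozen=True)
class VoLEstimate:
    """One published value-of-life benchmark, as stated in its source."""

    country: str
    row: int                      # row number within the country's source table
    sector: Sector
    source: str                   # issuing body, e.g. "NICE", "DfT"
    relevance: str                # free-text context for the benchmark
    measure: Measure
    stated: MoneyRange            # as printed, in local currency of stated_year
    stated_year: int
    currency: str
    needs_update: bool = False    # price-year adjustment required (editorial flag)
    in_comparison_set: bool = False       # enters the cross-sector comparison
    is_hta_reference: bool = False  # the country's health benchmark in that comparison
    hta_ref_bound: str = "both"   # "both" or "lower": which endpoint(s) the
    # comparison uses when the reference row is a range
    analysis_excluded: bool = False  # present in the source table but kept out
    # of the comparative analysis (e.g. post-search additions)
    adjusted: Optional[MoneyRange] = None  # filled by the price-adjustment stage

    def with_adjusted(self, value: MoneyRange) -> "VoLEstimate":
        return replace(self, adjusted=value)


_COLUMNS = [
    "country", "row", "sector", "source", "relevance", "measure",
    "stated_lower", "stated_upper", "stated_year", "currency",
    "needs_update", "in_comparison_set", "is_hta_reference", "hta_ref_bound",
    "analysis_excluded",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_bool(token: object, row: int, column: str) -> bool:
    t = str(token).strip().lower()
    if t not in _BOOL:
        raise RegistryError(f"row {row}, column {column}: not a boolean: {token!r}")
    return _BOOL[t]


def _parse_number(token: object, row: int, column: str) -> float:
    try:
        v = float(str(token).replace(",", ""))
    except ValueError:
        raise RegistryError(
            f"row {row}, column {column}: malformed numeric cell {token!r}"
        ) from None
    if math.isnan(v):
        raise RegistryError(f"row {row}, column {column}: missing numeric cell")
    return v


def load_registry(path: Union[str, Path]) -> list[VoLEstimate]:
    """Read a registry CSV; returns records in file order.

    Errors name the offending row (1-based, excluding the header) and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"registry header missing columns: {missing}")
    records = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        lower = _parse_number(rec["stated_lower"], i, "stated_lower")
        upper = _parse_number(rec["stated_upper"], i, "stated_upper")
        sector_token = str(rec["sector"]).strip().lower()
        try:
            sector = Sector(sector_token)
        except ValueError:
            raise RegistryError(f"row {i}: unknown sector {rec['sector']!r}") from None
        country = str(rec["country"]).strip()
        if not country:
            raise RegistryError(f"row {i}: empty country code")
        bound = str(rec["hta_ref_bound"]).strip().lower() or "both"
        if bound not in ("both", "lower"):
            raise RegistryError(f"row {i}: hta_ref_bound must be 'both' or 'lower'")
        records.append(VoLEstimate(
            country=country,
            row=int(_parse_number(rec["row"], i, "row")),
            sector=sector,
            source=str(rec["source"]).strip(),
            relevance=str(rec["relevance"]).strip(),
            measure=Measure.parse(str(rec["measure"])),
            stated=MoneyRange(lower, upper),
            stated_year=int(_parse_number(rec["stated_year"], i, "stated_year")),
            currency=str(rec["currency"]).strip(),
            needs_update=_parse_bool(rec["needs_update"], i, "needs_update"),
            in_comparison_set=_parse_bool(rec["in_comparison_set"], i, "in_comparison_set"),
            is_hta_reference=_parse_bool(rec["is_hta_reference"], i, "is_hta_reference"),
            hta_ref_bound=bound,
            analysis_excluded=_parse_bool(rec["analysis_excluded"], i, "analysis_excluded"),
        ))
    return records


def write_registry(records: Iterable[VoLEstimate], path: Union[str, Path]) -> None:
    """Write records back to CSV in the documented column order."""
    rows = []
    for r in records:
        rows.append({
            "country": r.country,
            "row": r.row,
            "sector": r.sector.value,
            "source": r.source,
            "relevance": r.relevance,
            "measure": r.measure.value,
            "stated_lower": f"{r.stated.lower:.12g}",
            "stated_upper": f"{r.stated.upper:.12g}",
            "stated_year": r.stated_year,
            "currency": r.currency,
            "needs_update": str(r.needs_update).lower(),
            "in_comparison_set": str(r.in_comparison_set).lower(),
            "is_hta_reference": str(r.is_hta_reference).lower(),
            "hta_ref_bound": r.hta_ref_bound,
            "analysis_excluded": str(r.analysis_excluded).lower(),
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class CountryParams:
    """Per-country conversion parameters.

    The annuity factor a(r, n) converts between a VSL and a VOLY. Where the
    underlying (discount rate, life expectancy) pair is known it is computed
    from the closed form; otherwise a derived factor recovered from the
    country's published VSL:VOLY pairs is carried in ``annuity_override``.

    ``rho`` is the VOLY:VOQ ratio (a life year is worth ``rho`` of a
    full-health QALY). ``rho_reciprocal`` is the multiplier used for the
    VOLY→VOQ direction; it defaults to 1/rho but may be pinned separately to
    mirror sources that rounded each direction of the ratio independently.
    """

    country: str
    rho: float = 0.91996
    rho_reciprocal: Optional[float] = None
    discount_rate: Optional[float] = None
    life_expectancy: Optional[float] = None
    reference_age: Optional[float] = None
    annuity_override: Optional[float] = None
    price_index: Mapping[int, float] = field(default_factory=dict)
    base_year: int = 2019

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise RegistryError(f"{self.country}: rho must be in (0, 1], got {self.rho}")
        if self.discount_rate is not None and not (0 <= self.discount_rate < 1):
            raise RegistryError(f"{self.country}: discount rate out of [0, 1)")
        if self.annuity_override is None and (
            self.discount_rate is None or self.remaining_years is None
        ):
            raise RegistryError(
                f"{self.country}: need either an annuity override or (discount rate,"
                " life expectancy, reference age)"
            )

    @property
    def remaining_years(self) -> Optional[float]:
        if self.life_expectancy is None or self.reference_age is None:
            return None
        n = self.life_expectancy - self.reference_age
        if n <= 0:
            raise RegistryError(f"{self.country}: non-positive remaining years {n}")
        return n

    @property
    def annuity(self) -> float:
        from .conversion import annuity_factor  # local import: no cycle at module load

        if self.annuity_override is not None:
            return self.annuity_override
        return annuity_factor(self.discount_rate, self.remaining_years)

    @property
    def voq_per_voly(self) -> float:
        return self.rho_reciprocal if self.rho_reciprocal is not None else 1.0 / self.rho


def load_params(path: Union[str, Path]) -> dict[str, CountryParams]:
    """Read the per-country parameter config (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    base_year = int(doc.get("base_year", 2019))
    defaults = doc.get("defaults", {})
    out: dict[str, CountryParams] = {}
    for code, entry in doc["countries"].items():
        merged = {**defaults, **(entry or {})}
        out[str(code)] = CountryParams(
            country=str(code),
            rho=float(merged.get("rho", 0.91996)),
            rho_reciprocal=(None if merged.get("rho_reciprocal") is None
                            else float(merged["rho_reciprocal"])),
            discount_rate=(None if merged.get("discount_rate") is None
                           else float(merged["discount_rate"])),
            life_expectancy=(None if merged.get("life_expectancy") is None
                             else float(merged["life_expectancy"])),
            reference_age=(None if merged.get("reference_age") is None
                           else float(merged["reference_age"])),
            annuity_override=(None if merged.get("annuity_factor") is None
                              else float(merged["annuity_factor"])),
            price_index={int(y): float(v)
                         for y, v in (merged.get("price_index") or {}).items()},
            base_year=int(merged.get("base_year", base_year)),
        )
    return out


def save_params(params: Mapping[str, CountryParams], path: Union[str, Path]) -> None:
    doc: dict = {"base_year": None, "countries": {}}
    years = {p.base_year for p in params.values()}
    doc["base_year"] = years.pop() if len(years) == 1 else 2019
    for code, p in params.items():
        entry: dict = {"rho": p.rho}
        if p.rho_reciprocal is not None:
            entry["rho_reciprocal"] = p.rho_reciprocal
        if p.discount_rate is not None:
            entry["discount_rate"] = p.discount_rate
        if p.life_expectancy is not None:
            entry["life_expectancy"] = p.life_expectancy
        if p.reference_age is not None:
            entry["reference_age"] = p.reference_age
        if p.annuity_override is not None:
            entry["annuity_factor"] = p.annuity_override
        if p.price_index:
            entry["price_index"] = {int(y): float(v) for y, v in p.price_index.items()}
        if p.base_year != doc["base_year"]:
            entry["base_year"] = p.base_year
        doc["countries"][code] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``record_index`` is 1-based file order."""

    record_index: Optional[int]
    field: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:
        if self.ok:
            return "registry valid: no findings"
        lines = [f"{len(self.findings)} finding(s):"]
        for f in self.findings:
            where = f"record {f.record_index}" if f.record_index else "registry"
            lines.append(f"  {where} [{f.field}]: {f.message}")
        return "\n".join(lines)


def validate_registry(
    records: Iterable[VoLEstimate],
    params: Mapping[str, CountryParams],
) -> ValidationReport:
    """Check record invariants and cross-references; findings are data, not errors."""
    report = ValidationReport()
    records = list(records)
    ref_counts: dict[str, int] = {}
    for i, r in enumerate(records, start=1):
        if r.stated.lower <= 0:
            report.findings.append(Finding(i, "stated", "values must be strictly positive"))
        if r.country not in params:
            report.findings.append(Finding(i, "country", f"no parameters for {r.country!r}"))
        else:
            p = params[r.country]
            if r.needs_update:
                for year in (r.stated_year, p.base_year):
                    if year not in p.price_index:
                        report.findings.append(Finding(
                            i, "price_index",
                            f"{r.country} series lacks year {year} needed for adjustment",
                        ))
        if r.is_hta_reference:
            if r.sector is not Sector.HEALTH:
                report.findings.append(Finding(
                    i, "is_hta_reference", "reference flag on a non-health record"))
            ref_counts[r.country] = ref_counts.get(r.country, 0) + 1
    for country in sorted({r.country for r in records}):
        n_ref = ref_counts.get(country, 0)
        has_t8 = any(r.country == country and r.in_comparison_set for r in records)
        if has_t8 and n_ref == 0:
            report.findings.append(Finding(
                None, "is_hta_reference", f"{country}: comparison rows but no health reference"))
        if n_ref > 2:
            report.findings.append(Finding(
                None, "is_hta_reference",
                f"{country}: {n_ref} reference rows (at most two point rows may be pooled)"))
    return report


def default_registry() -> list[VoLEstimate]:
    """The packaged six-country benchmark registry."""
    with resources.as_file(resources.files("lifevalues.data") / "registry.csv") as p:
        return load_registry(p)


def default_params() -> dict[str, CountryParams]:
    """The packaged per-country conversion parameters."""
    with resources.as_file(resources.files("lifevalues.data") / "country_params.yaml") as p:
        return load_params(p)
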