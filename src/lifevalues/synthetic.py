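"""Synthetic registries and allocation problems with known ground truth.

The generator emulates what the real registry looks like after a document
search: per-country benchmark rows stated on a native measure (VSL, VOLY or
QALY), with older values carrying an inflation gap to the base year, and
every derived column fabricated by the same forward conversion chain and
whole-unit rounding the pipeline itself uses. Because the generating
parameters (annuity factor, VOLY:QALY ratio, inflation factors) are known
and returned separately, every pipeline stage can be tested end-to-end and
parameter-recovery operations can be checked against truth. It makes no
attempt to mimic search noise (missing thresholds, ambiguous sourcing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._money import MoneyRange, round_half_away
from .allocation import AllocationProblem, Department, PowerProduction
from .conversion import annuity_factor
from .registry import CountryParams, Measure, Sector, VoLEstimate

__all__ = [
    "SyntheticSpec",
    "SyntheticRegistry",
    "generate_registry",
    "SyntheticAllocation",
    "generate_allocation_problems",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions under which synthetic registries are drawn."""

    seed: int
    n_countries: int = 6
    n_estimates_per_country: int = 8
    share_ranges: float = 0.25          # fraction of rows stated as a range
    base_year: int = 2019
    year_span: tuple[int, int] = (2000, 2019)
    discount_range: tuple[float, float] = (0.005, 0.05)
    life_expectancy_range: tuple[float, float] = (78.0, 86.0)
    reference_age: float = 40.0
    rho_range: tuple[float, float] = (0.85, 1.0)
    voq_range: tuple[float, float] = (15_000.0, 120_000.0)
    voly_range: tuple[float, float] = (15_000.0, 300_000.0)
    vsl_range: tuple[float, float] = (1e6, 8e6)
    inflation_range: tuple[float, float] = (1.0, 1.6)

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.n_estimates_per_country < 3:
            raise ValueError("need at least one country and three rows per country")
        if not (0 <= self.share_ranges <= 1):
            raise ValueError("share_ranges must lie in [0, 1]")
        if not (0 < self.rho_range[0] <= self.rho_range[1] <= 1):
            raise ValueError("rho range must lie in (0, 1]")


@dataclass
class SyntheticRegistry:
    records: list[VoLEstimate]
    params: dict[str, CountryParams]
    truth: dict[str, dict] = field(default_factory=dict)
    expected_pcts: dict[tuple[str, str, int], tuple[int, int]] = field(default_factory=dict)
    # key: (country, sector value, running index) -> integer percent range


def _chain(value: float, measure: Measure, a: float, rho: float) -> dict[Measure, float]:
    """Forward conversion chain, unrounded (the generator's own oracle)."""
    if measure is Measure.VOQ:
        return {Measure.VOQ: value, Measure.VOLY: value * rho, Measure.VSL: value * a / rho}
    if measure is Measure.VOLY:
        return {Measure.VOLY: value, Measure.VSL: value * a, Measure.VOQ: value / rho}
    return {Measure.VSL: value, Measure.VOLY: value / a, Measure.VOQ: value / (a * rho)}


def generate_registry(spec: SyntheticSpec) -> SyntheticRegistry:
    """Draw a registry with known conversion parameters; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[VoLEstimate] = []
    params: dict[str, CountryParams] = {}
    truth: dict[str, dict] = {}
    expected: dict[tuple[str, str, int], tuple[int, int]] = {}

    for ci in range(spec.n_countries):
        code = f"S{ci + 1:02d}"
        r = rng.uniform(*spec.discount_range)
        le = rng.uniform(*spec.life_expectancy_range)
        rho = rng.uniform(*spec.rho_range)
        a = annuity_factor(r, le - spec.reference_age)
        years = np.arange(spec.year_span[0], spec.year_span[1] + 1)
        # monotone inflation: level declines with distance from the base year
        factors = {int(y): float(f) for y, f in zip(
            years, np.sort(rng.uniform(*spec.inflation_range, len(years)))[::-1])}
        factors[spec.base_year] = 1.0
        params[code] = CountryParams(
            country=code,
            rho=rho,
            rho_reciprocal=None,  # generator is internally consistent: 1/rho
            discount_rate=r,
            life_expectancy=le,
            reference_age=spec.reference_age,
            price_index={y: 1.0 / f for y, f in factors.items()},
            base_year=spec.base_year,
        )
        truth[code] = {"discount_rate": r, "life_expectancy": le, "rho": rho,
                       "annuity": a, "inflation": factors}

        n = spec.n_estimates_per_country
        sectors = [Sector.HEALTH, Sector.TRANSPORT, Sector.ENVIRONMENT]
        sectors += list(rng.choice([s.value for s in Sector], n - 3))
        sectors = [Sector(s) for s in sectors]
        health_ref_voq = None
        comparison_idx = 0
        for row, sector in enumerate(sectors, start=1):
            if sector is Sector.HEALTH:
                measure = Measure.VOQ
            else:
                measure = Measure(rng.choice([Measure.VSL.value, Measure.VOLY.value]))
            lo = {
                Measure.VOQ: rng.uniform(*spec.voq_range),
                Measure.VOLY: rng.uniform(*spec.voly_range),
                Measure.VSL: rng.uniform(*spec.vsl_range),
            }[measure]
            lo = float(round_half_away(lo))
            hi = lo
            if rng.uniform() < spec.share_ranges:
                hi = float(round_half_away(lo * rng.uniform(1.2, 3.0)))
            year = int(rng.choice(years))
            needs_update = year != spec.base_year and rng.uniform() < 0.5
            f = factors[year] if needs_update else 1.0
            is_ref = sector is Sector.HEALTH and health_ref_voq is None
            in_t8 = sector in (Sector.TRANSPORT, Sector.ENVIRONMENT)
            records.append(VoLEstimate(
                country=code, row=row, sector=sector,
                source=f"SRC{row}", relevance="synthetic benchmark",
                measure=measure,
                stated=MoneyRange(lo, hi), stated_year=year, currency="XSY",
                needs_update=needs_update, in_comparison_set=in_t8,
                is_hta_reference=is_ref,
            ))
            adj = (float(round_half_away(lo * f)), float(round_half_away(hi * f)))
            if is_ref:
                health_ref_voq = tuple(
                    round_half_away(_chain(v, measure, a, rho)[Measure.VOQ]) for v in adj)
            if in_t8:
                for v in (adj if adj[0] != adj[1] else adj[:1]):
                    voq = round_half_away(_chain(v, measure, a, rho)[Measure.VOQ])
                    expected[(code, sector.value, comparison_idx)] = voq
                    comparison_idx += 1
        # generator's own percentage arithmetic (same rounding rule)
        for key, voq in list(expected.items()):
            if key[0] != code:
                continue
            expected[key] = (
                round_half_away(100.0 * health_ref_voq[0] / voq),
                round_half_away(100.0 * health_ref_voq[1] / voq),
            )
        truth[code]["health_ref_voq"] = health_ref_voq

    return SyntheticRegistry(records=records, params=params, truth=truth,
                             expected_pcts=expected)


@dataclass
class SyntheticAllocation:
    problem: AllocationProblem
    optimum: np.ndarray   # closed-form Lagrange solution
    welfare: float


def generate_allocation_problems(
    spec: SyntheticSpec, n_problems: int = 5
) -> list[SyntheticAllocation]:
    """Power-form problems with a shared exponent, whose optimum is analytic.

    With h_j = c_j m**beta and a_j = d_j m**beta, the first-order conditions
    give m_j proportional to (upsilon*c_j + d_j)**(1/(1-beta)).
    """
    rng = np.random.default_rng(spec.seed + 1)
    out = []
    for _ in range(n_problems):
        J = int(rng.integers(2, 5))
        beta = float(rng.uniform(0.3, 0.8))
        c = rng.uniform(0.5, 5.0, J)
        d = rng.uniform(0.5, 5.0, J)
        upsilon = float(rng.uniform(0.2, 3.0))
        M = float(rng.uniform(1e6, 1e8))
        departments = [
            Department(
                name=f"dept{j}",
                health=PowerProduction(c[j], beta),
                amenity=PowerProduction(d[j], beta),
            ) for j in range(J)
        ]
        problem = AllocationProblem(budget=M, departments=departments, upsilon=upsilon)
        w = (upsilon * c + d) ** (1.0 / (1.0 - beta))
        optimum = M * w / w.sum()
        out.append(SyntheticAllocation(
            problem=problem, optimum=optimum, welfare=problem.welfare(optimum)))
    return out
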