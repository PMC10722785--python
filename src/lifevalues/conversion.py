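"""Annuity-based conversion algebra between VSL, VOLY and VOQ.

A VSL and a VOLY are linked by the discounted annuity over remaining life
expectancy, a(r, n) = (1 - (1+r)^-n) / r: a statistical life is worth
``a`` discounted life years. A VOLY and a VOQ (value of a QALY) are linked
by the ratio rho <= 1: a life year in average health is worth ``rho`` of a
full-health QALY.

The published tables this package reproduces apply the chain
direction-dependently, and for QALY-source rows compute
VSL = VOQ * a / rho rather than the internally consistent VOQ * rho * a.
The default mode reproduces that convention (and warns); ``strict=True``
switches to the consistent chain. ``voq_vsl_diagnostic`` reports both
candidates, which differ by the factor 1/rho**2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._money import MoneyRange, round_half_away
from .registry import CountryParams, Measure

__all__ = [
    "annuity_factor",
    "convert",
    "ConversionTriple",
    "ConversionConventionWarning",
    "voq_vsl_diagnostic",
    "implied_ratio",
    "implied_annuity",
    "RecoveredParameter",
]


class ConversionConventionWarning(UserWarning):
    """Emitted when the source tables' inconsistent VOQ→VSL chain is used."""


def annuity_factor(r: float, n: float) -> float:
    """Present value of a unit annual payment over ``n`` years at rate ``r``.

    Continuous at r = 0, where the value is exactly ``n``. Satisfies
    0 < a <= n for r >= 0.
    """
    import math

    if n <= 0:
        raise ValueError(f"remaining years must be positive, got {n}")
    if r < 0:
        raise ValueError(f"discount rate must be non-negative, got {r}")
    if n * r < 1e-14:  # zero-discount limit, incl. subnormal rates
        return float(n)
    # -expm1(-n*log1p(r))/r == (1-(1+r)^-n)/r, stable as r -> 0
    return -math.expm1(-n * math.log1p(r)) / r


def invert_annuity(a: float, r: float) -> float:
    """Remaining years ``n`` such that annuity_factor(r, n) == a (r > 0)."""
    import math

    if r <= 0:
        return a
    x = 1.0 - r * a
    if x <= 0:
        raise ValueError(f"annuity {a} unattainable at rate {r} (perpetuity is {1/r})")
    return -math.log(x) / math.log(1.0 + r)


@dataclass(frozen=True)
class ConversionTriple:
    """One estimate expressed simultaneously on all three measures.

    ``vsl``/``voly``/``voq`` are rounded to whole currency units as published
    values are; the ``raw_*`` companions keep the unrounded chain values for
    round-tripping and diagnostics.
    """

    vsl: MoneyRange
    voly: MoneyRange
    voq: MoneyRange
    source_measure: Measure
    country: str
    raw_vsl: Optional[MoneyRange] = None
    raw_voly: Optional[MoneyRange] = None
    raw_voq: Optional[MoneyRange] = None

    def get(self, measure: Measure) -> MoneyRange:
        return {Measure.VSL: self.vsl, Measure.VOLY: self.voly, Measure.VOQ: self.voq}[measure]


def convert(
    value: MoneyRange,
    measure: Measure,
    params: CountryParams,
    strict: bool = False,
) -> ConversionTriple:
    """Express ``value`` (on ``measure``) as a (VSL, VOLY, VOQ) triple.

    Applied elementwise to range endpoints; every output is rounded to the
    nearest whole currency unit, half away from zero. The source measure's
    slot echoes the (rounded) input.
    """
    if value.lower <= 0:
        raise ValueError("value must be strictly positive")
    a = params.annuity
    rho = params.rho
    recip = params.voq_per_voly
    if measure is Measure.VSL:
        raw_voly = value.map(lambda v: v / a)
        raw = (value, raw_voly, raw_voly.map(lambda v: v * recip))
    elif measure is Measure.VOLY:
        raw = (value.map(lambda v: v * a), value, value.map(lambda v: v * recip))
    elif measure is Measure.VOQ:
        if strict:
            raw_vsl = value.map(lambda v: v * rho * a)
        else:
            warnings.warn(
                "QALY-source VSL uses the published convention VOQ*a/rho, which is "
                "inconsistent with the VOLY-source chain by the factor 1/rho**2; "
                "pass strict=True for the consistent chain",
                ConversionConventionWarning,
                stacklevel=2,
            )
            raw_vsl = value.map(lambda v: v * a / rho)
        raw = (raw_vsl, value.map(lambda v: v * rho), value)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown measure {measure!r}")
    return ConversionTriple(
        vsl=raw[0].rounded(),
        voly=raw[1].rounded(),
        voq=raw[2].rounded(),
        source_measure=measure,
        country=params.country,
        raw_vsl=raw[0],
        raw_voly=raw[1],
        raw_voq=raw[2],
    )


def voq_vsl_diagnostic(value: float, params: CountryParams) -> dict[str, float]:
    """Both candidate VSLs for a QALY-source value, and their ratio.

    ``published`` follows the source tables (VOQ * a / rho); ``consistent``
    follows the VOLY-source chain applied to VOLY = VOQ * rho. Their ratio is
    1/rho**2 identically.
    """
    a, rho = params.annuity, params.rho
    published = value * a / rho
    consistent = value * rho * a
    return {
        "published": published,
        "consistent": consistent,
        "ratio": published / consistent,
        "expected_ratio": 1.0 / rho**2,
    }


@dataclass(frozen=True)
class RecoveredParameter:
    """A parameter recovered from printed column pairs: mean and spread."""

    value: float
    max_abs_deviation: float


def _recover(ratios: Sequence[float]) -> RecoveredParameter:
    if not ratios:
        raise ValueError("need at least one pair")
    mean = sum(ratios) / len(ratios)
    return RecoveredParameter(mean, max(abs(x - mean) for x in ratios))


def implied_ratio(pairs: Iterable[tuple[float, float]]) -> RecoveredParameter:
    """Recover rho from (VOQ, VOLY) pairs as the mean of VOLY/VOQ."""
    pairs = list(pairs)
    if any(voq <= 0 or voly <= 0 for voq, voly in pairs):
        raise ValueError("pairs must be strictly positive")
    return _recover([voly / voq for voq, voly in pairs])


def implied_annuity(pairs: Iterable[tuple[float, float]]) -> RecoveredParameter:
    """Recover the annuity factor from (VSL, VOLY) pairs as the mean of VSL/VOLY."""
    pairs = list(pairs)
    if any(vsl <= 0 or voly <= 0 for vsl, voly in pairs):
        raise ValueError("pairs must be strictly positive")
    return _recover([vsl / voly for vsl, voly in pairs])


def rescaled_annuity(params: CountryParams, age: float, fallback_rate: float = 0.015) -> float:
    """Annuity factor at a reference age other than the baseline 40.

    Where the country's (r, LE) are known the closed form is rebuilt at
    n = LE - age. Otherwise the derived factor is rescaled multiplicatively
    by the ratio of closed-form factors at the new vs baseline horizon,
    with the horizon inferred by inverting the derived factor at
    ``fallback_rate`` (a documented fallback for countries whose inputs
    are not published).
    """
    baseline_age = params.reference_age if params.reference_age is not None else 40.0
    if params.discount_rate is not None and params.remaining_years is not None:
        n = params.life_expectancy - age
        if n <= 0:
            raise ValueError(f"age {age} at or beyond life expectancy {params.life_expectancy}")
        return annuity_factor(params.discount_rate, n)
    a0 = params.annuity
    n0 = invert_annuity(a0, fallback_rate)
    n = n0 + (baseline_age - age)
    if n <= 0:
        raise ValueError(f"age {age} leaves no remaining life years (baseline horizon {n0:.1f})")
    return a0 * annuity_factor(fallback_rate, n) / annuity_factor(fallback_rate, n0)
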